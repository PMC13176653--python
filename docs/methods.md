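# Methods

This note documents the models implemented in `ifnscope`, the parameter
choices that matter, what the synthetic data generator does and does not
emulate, and the numerical decisions taken where the design was open.

## Gene positions, neighbourhoods and the IFN keyword filter

Every gene is reduced to a single coordinate, the midpoint
⌈(start+end)/2⌉ on 1-based inclusive (GFF3) coordinates, rounded half-up.
Half-up rounding is deterministic but not mirror-symmetric: reflecting a
chromosome maps a half-integer midpoint to the base one position off,
because both orientations round upward. Nothing downstream depends on
sub-base symmetry.

The *neighbourhood* of a focal gene (or IFN cluster) is the n = 10
non-IFN genes on the same chromosome nearest by midpoint distance,
nearest first. Distance ties break on the smaller start coordinate, then
the lexicographically smaller symbol, so outputs are reproducible.
Neighbourhoods with fewer than n available genes are flagged truncated.

Annotated type I IFNs are recognised by substring rules over the
concatenated product/description/abbreviation text: the text must
contain "type i" and "interferon"/"ifn" (case-insensitive), must not
contain "type ii", "type iii", "factor", or the stems "induc"/"stimulat"
(covering induced/inducible and stimulated/stimulator — this is what
keeps interferon-*induced* effector genes such as IFIT/ISG/OASL family
members out of the positive set), and must not be flagged pseudogene or
low-quality protein. Gene-symbol harmonisation across databases has no
recoverable algorithm, so it is a pluggable hook: an explicit mapping
table plus a default preference order (symbol attribute, else
abbreviation, else a slug of the product text).

## ORF extension

Translated-homology hits arrive as 12-column tabular rows; descending
subject coordinates mean a minus-strand hit and are normalised
ascending. A hit is extended in its own reading frame (the span must be
a whole number of codons): walking upstream codon-by-codon from the
codon immediately 5′ of the hit, the first in-frame ATG becomes the
start; walking downstream from the codon immediately 3′ of the hit, the
first in-frame stop (TAA/TAG/TGA) ends the ORF. An in-frame stop met
before any ATG, an ambiguity code (N) in either walk, or exhaustion of
the 6 000 bp per-direction budget abandons the candidate. The budget is
generous — amniote type I IFN ORFs are ~500–600 bp — and configurable.

Two consequences are deliberate. Codons *inside* the aligned span are
never start candidates, so internal methionines in the aligned region
cannot truncate the ORF; a hit whose alignment begins exactly at the
initiator Met is therefore extended from upstream context and may be
dropped — in practice translated hits align within the mature protein.
Candidates are treated as intronless, matching the retroposed origin of
amniote type I IFNs; spliced IFN variants are out of scope.

Surviving candidates are screened against annotated IFN intervals (any
1 bp overlap on the same chromosome removes the candidate as already
known), deduplicated on identical (chromosome, start, end, strand), and
named `{species}_{chromosome}_POS{position}` from the midpoint rule
above.

## APAAC features

The amphiphilic pseudo amino acid composition of a protein P of length
L is the 20+2λ vector combining residue frequencies f_i with correlation
factors

τ_j = (1/(L−k)) Σ_{n=1..L−k} s*(R_n)·s*(R_{n+k}),  k = ⌈j/2⌉,

where s* is the Z-scored Tanford hydrophobicity scale for odd j and the
Z-scored Hopp–Woods hydrophilicity scale for even j; both scales ship as
constants and can be overridden. Z-scoring uses the population (divide-
by-20) standard deviation; with that convention normalisation is exactly
idempotent. The tier-to-lag map k = ⌈j/2⌉ realises the canonical
interleaving (tiers 2k−1, 2k are the lag-k hydrophobicity and
hydrophilicity factors), which is the standard reading of "k = j/2,
rounded". Both factors in the lag product are normalised values.

All 20+2λ components share the denominator D = Σf + wΣτ, so every valid
vector sums to exactly 1 — the property tests lean on this identity. D
can in principle approach zero when wΣτ ≈ −1; |D| < 1e-8 raises rather
than dividing. Defaults λ = 30 (requires L ≥ 31) and w = 0.05.
Sequences containing B/J/O/U/X/Z are rejected, not imputed; batch
featurisation offers a skip-and-log mode.

## The classifier

Training data are annotated IFN proteins (positives) against their
neighbourhood-gene proteins (negatives). The model is an L2-penalised
logistic regression optimised by stochastic average gradient to
tolerance 1e-6 with a fixed seed; any deterministic convex solver
reaching that tolerance would give the same coefficients to numerical
precision.

Features are standardised (per-feature mean/SD, stored in the model and
re-applied at prediction) before fitting. APAAC components live on a
~1/dimension scale, so a unit L2 penalty applied to raw features drives
a desk-scale problem to the class prior, and SAG's convergence rate
degrades on unequally scaled inputs; standardisation also puts the
pruning rule below on a common scale. The L2 strength default is 1.0 in
the standardised space, exposed as configuration. No class reweighting
is applied by default (the imbalance between IFNs and their roughly
2.6× more numerous neighbours is left as-is, with a weighting flag for
users who want it).

Dimensionality reduction prunes feature u when |ω_u| falls below the
mean of all |ω| (boundary kept: equal coefficients all survive — with a
signed mean the rule could become vacuous), then refits on the
survivors; both dimensionalities are recorded in model metadata.
Refitting after pruning, rather than masking the original fit, is the
standard select-from-model usage. Evaluation reports confusion counts at
a probability threshold of 0.5 plus precision, recall, F1, accuracy and
ROC-AUC (trapezoidal over all thresholds; ties credited 0.5, i.e. the
Mann–Whitney statistic). Cross-validation is stratified 5-fold with
seeded shuffling — plain k-fold can starve the minority class at these
sample sizes; the pooled report recomputes count-based metrics from the
summed confusion table and averages AUC over folds. Models serialise to
a single JSON document (coefficients, mask, scaler, seed) independent of
any library's pickle format.

## Conserved-locus detection

Within each species and chromosome, IFN genes with no intervening
non-IFN gene are merged into one cluster; chains are built per cluster
(not per gene), so a 20-copy tandem array contributes exactly one chain
and cannot inflate its flanks' importance. The chain links the cluster
to the symbols of the 10 genes nearest the cluster's spanning-interval
midpoint. The knowledge graph has one node per distinct neighbour
symbol (global merge) and one per cluster, with star edges from each
cluster to its chain's symbols; a symbol's degree therefore counts the
IFN clusters it flanks across the whole dataset. When one species
contributes several chains flanking the same symbol, each chain counts;
a species-counting mode is available behind a flag.

Extraction loops: take the maximum-degree symbol (ties broken
lexicographically for determinism); if its degree is strictly greater
than the threshold (default 15), emit it, delete every chain containing
it and any symbol node thereby orphaned, and recompute; otherwise stop.
Each iteration removes at least one chain, so the loop terminates within
the chain count. Locus assignment is per *gene*: an IFN gene belongs to
an extracted locus only if that symbol sits in the gene's own 10-gene
neighbourhood, the nearest such locus winning; genes matching no locus
fall into the exception category, which is how interchromosomal
duplicates surface. The summary reports per-locus annotated/unannotated
counts and 100 × (total − exceptions)/total to one decimal.

Locus analysis runs on annotated genes *plus* the IFN genes recovered by
the discovery stage. This matters for single-copy loci: if the lone
IFN at a locus is unannotated in some species and only annotated genes
are fed in, that species contributes no chain and the locus degree drops
below threshold for reasons that have nothing to do with synteny.

## The synthetic pangenome

The generator emulates the data regime the pipeline assumes, at desk
scale. Each species (default 18: 8 mammal-like, 6 bird-like, 4
reptile-like) carries one main chromosome with three anchor loci.
Per-clade IFN copy numbers follow the reported single/multi-copy
pattern: the HACD4-like locus is multi-copy in mammals (4–8) and
reptiles (3–6) but single-copy in birds; the UBAP2-like locus expands
only in birds (2–4); the MOB3B-like locus is single-copy everywhere.
Arrays of four or more copies are interrupted by one embedded non-IFN
gene, splitting them into two clusters. At the default scale every
species carries at least one copy at each locus: with 18 species a locus
can only clear the strictly-greater-than-15 degree gate if nearly every
species contributes a chain, so the "not found in most mammals" pattern
seen at UBAP2 in the full-scale data is not reproduced at n = 18 (it
would need the full species count, not a different algorithm).

The anchor gene always sits immediately beside its IFN cluster — being
recurrently adjacent is what makes it the conserved locus — while each
member of the locus's 14-symbol flanking pool is retained independently
per species with probability 0.95 (modelling annotation variability of
the neighbourhood), interleaved at species-specific positions with six
species-private filler genes. A retained flank thus lands inside the
10-gene neighbourhood less than half the time, keeping flank degrees
well under the threshold while anchor degrees track the chain count. A
separate `anchor_retention` knob (default 1.0) can drop anchor genes
from annotations to study the failure mode; with anchor dropout p and
one chain per species the anchor degree is Binomial(18, p), and at
p = 0.95 the probability of clearing the gate is only 0.942 per locus —
the regime the default deliberately avoids.

IFN proteins are the fixed 141-residue synthetic family consensus (Met
only at position 1) with independent per-residue substitution at the
configured rate (default 0.05); fillers are random proteins of 120–250
residues. Nucleotide sequence is produced by a fixed codon per amino
acid plus TAA — codon-usage realism is irrelevant to an amino-acid-
composition pipeline. A configurable fraction of IFN copies (default
0.15, roughly the unannotated share in the motivating full-scale data)
is omitted from the GFF but present in sequence; an exact-count override
exists for experiments that require, e.g., exactly 100 planted
unannotated copies. One IFN copy can be duplicated onto a second
chromosome between two novel flanking symbols. Two decoy genes per
species ("interferon-induced…", "interferon gamma type II…") exercise
the keyword filter. Pseudo-hits cover a random internal in-frame window
of each IFN ORF, shrunk up to 30 bp per end but never past an internal
Met on the 5′ side, so extension provably recovers the planted interval;
minus-strand hits use descending subject coordinates.

Seeding: one config seed; per-species streams are derived as
(seed, species-index, purpose), so adding species never perturbs earlier
ones, and the annotation-only fast path draws layout coordinates from
the same streams as the full run.

What passing tests on this generator show — and what they do not: the
synthetic families are mutation clouds around one consensus with no
indels, no tree-structured divergence, no pseudogenes and no spliced
genes, and negatives are composition-matched shuffles (or an unrelated
synthetic family). Clean separation here demonstrates that the plumbing,
the feature algebra and the graph algorithm are correct, not that the
classifier's error rates transfer to real, deeply diverged genomes.

## Percent identity

Identity between two aligned sequences is 100 × matches over columns
ungapped in both; columns gapped in either sequence are excluded from
the denominator, and pairs with zero ungapped columns score 0 with a
flag. Alignment itself is an input (aligned FASTA). The rank-sum
(Mann–Whitney) comparison offered for within- vs between-group identity
distributions is a convenience choice of this package.

## Problem sizes

Defaults were chosen so the whole suite and the acceptance script each
run in well under a minute on one CPU: 18-species pangenomes of ~1 700
genes, 100-seed locus-recovery sweeps on the annotation-only fast path,
five discovery pangenomes with 100 planted unannotated copies each, and
brute-force oracles capped at 500 examples (AUC) and 50 chains
(degrees).

## Known limitations

* Gene-symbol revision is only as good as the supplied mapping; symbol
  identity is the sole orthology signal in the locus detector.
* Hits aligning from the initiator Met extend through upstream context
  (see above); candidates containing in-frame stops within the aligned
  region are dropped rather than repaired.
* The locus detector's degree gate is calibrated to dataset size: with
  fewer than 16 contributing species-chains a locus cannot be called
  conserved at the default threshold.
* Identity values depend on the aligner's gap placement; the matrix
  module makes the denominator convention explicit but cannot undo an
  upstream misalignment.
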