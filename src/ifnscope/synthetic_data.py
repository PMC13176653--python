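"""Seeded multi-species pangenome simulator.

Generates per-species gene annotations (GFF3), genome sequence (FASTA),
protein sequences and a truth table exhibiting the structures the
discovery pipeline assumes:

* three anchor loci whose anchor genes are flanked, across species, by a
  shared pool of neighbour symbols retained per species with a configured
  probability (modelling annotation variability of the neighbourhood);
* tandem IFN clusters beside each anchor with clade-specific copy numbers
  (multi-copy arrays may be interrupted by an embedded non-IFN gene);
* IFN copies present in genomic sequence but omitted from the annotation
  (the "unannotated" genes the classifier must rediscover);
* optionally one interchromosomal duplication of an IFN gene placed
  between two novel flanking symbols on a separate chromosome;
* decoy genes whose descriptions mention interferons without being type I
  IFN genes, exercising the keyword filters.

A single seed drives everything; per-species streams are derived
deterministically so adding species does not perturb earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_io import GeneRecord
from .apaac import AMINO_ACIDS
from .errors import ConfigError

#: one fixed codon per amino acid; none is a stop codon, M ↦ ATG
BACK_TRANSLATION = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: synthetic type I IFN family consensus (not a database sequence); starts
#: with the initiator Met and carries no other Met
DEFAULT_CONSENSUS = (
    "M"
    "SLDKTHPLIRGWNEACQFVS"
    "TEDLAKQYGIPLEHVRNWTS"
    "KAGEVFDICRNQLTPWHSYA"
    "QVNDLERTGKFSICPWHLAY"
    "EDSKIVRGNQTLAPWFCHYE"
    "GARLNDTKQIVSEPWFYHCL"
    "TSGANDLKEQRIVPWFSHYE"
)

#: second, unrelated synthetic family used for the "unrelated-family"
#: negative source
UNRELATED_CONSENSUS = (
    "M"
    "KVEQWFAGHDNLTSYRIPCE"
    "NHGSLTAWVQKEDFYRIPCA"
    "DWQKYLHGVTFENSARIPCE"
    "GHWFKLYQVDNTSEARIPCA"
    "SQHYWVKFGLDNTEARIPCE"
    "TNGHKWQYVFLDSEARIPCA"
)

_DEFAULT_CLADE_FRACTIONS = {"Mammalia": 8 / 18, "Aves": 6 / 18, "Reptilia": 4 / 18}


@dataclass(frozen=True)
class AnchorSpec:
    """One conserved locus: its anchor symbol, neighbour pool, and the
    per-species retention probability of each pool gene.

    ``copy_number`` maps clade name to an inclusive (lo, hi) range of IFN
    copies planted beside the anchor in species of that clade.
    """

    symbol: str
    flank_pool: tuple[str, ...]
    retention: float = 0.95
    copy_number: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {"Mammalia": (1, 1), "Aves": (1, 1), "Reptilia": (1, 1)}
    )


def default_anchors() -> tuple[AnchorSpec, ...]:
    """Three anchor loci mirroring the HACD4 / MOB3B / UBAP2 regime:
    the HACD4-like locus carries multi-copy arrays in mammals and
    reptiles, the UBAP2-like locus expands in birds, and the MOB3B-like
    locus stays single-copy everywhere."""
    return (
        AnchorSpec(
            symbol="HACD4",
            flank_pool=(
                "MTAP", "CDKN2A", "CDKN2B", "DMRTA1", "ELAVL2", "TUSC1", "IZUMO3",
                "KLHL9", "PLAA", "IFT74", "LRRC19", "TCF24", "CAAP1", "PLIN2",
            ),
            copy_number={"Mammalia": (4, 8), "Aves": (1, 1), "Reptilia": (3, 6)},
        ),
        AnchorSpec(
            symbol="MOB3B",
            flank_pool=(
                "C9ORF72", "LINGO2", "TEK", "EQTN", "ACO1", "DDX58", "TOPORS",
                "NDUFB6", "TAF1L", "APTX", "DNAJA1", "SMU1", "B4GALT1", "BAG1",
            ),
            copy_number={"Mammalia": (1, 1), "Aves": (1, 1), "Reptilia": (1, 1)},
        ),
        AnchorSpec(
            symbol="UBAP2",
            flank_pool=(
                "DCAF10", "FAM219A", "UNC13B", "RUSC2", "TESK1", "CD72", "SIT1",
                "FAM214B", "STOML2", "PIGO", "VCP", "NPR2", "SPAG8", "HINT2",
            ),
            copy_number={"Mammalia": (1, 1), "Aves": (2, 4), "Reptilia": (1, 1)},
        ),
    )


@dataclass
class SimConfig:
    """Study conditions for one simulated pangenome."""

    seed: int = 0
    n_species: int = 18
    anchors: tuple[AnchorSpec, ...] = field(default_factory=default_anchors)
    family_consensus: str = DEFAULT_CONSENSUS
    mutation_rate: float = 0.05
    negative_source: str = "shuffled"  # or "unrelated-family"
    unannotated_fraction: float = 0.15
    unannotated_count: int | None = None
    interchrom_dup: bool = True
    #: probability the anchor gene itself is retained in a species'
    #: annotation; 1.0 by default — the anchors are, by construction, the
    #: conserved loci
    anchor_retention: float = 1.0
    clade_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CLADE_FRACTIONS)
    )
    fillers_per_block: int = 6
    private_per_locus: int = 6
    neighborhood_size: int = 10

    def __post_init__(self) -> None:
        for p in (
            self.mutation_rate, self.unannotated_fraction, self.anchor_retention,
            *(a.retention for a in self.anchors),
        ):
            if not 0 <= p <= 1:
                raise ConfigError(f"probability {p} outside [0, 1]")
        if self.mutation_rate >= 1:
            raise ConfigError("mutation rate must be < 1")
        if len(self.family_consensus) < 31:
            raise ConfigError("family consensus must be at least 31 residues")
        if not self.family_consensus.startswith("M"):
            raise ConfigError("family consensus must start with Met")
        for anchor in self.anchors:
            if len(anchor.flank_pool) < self.neighborhood_size:
                raise ConfigError(
                    f"anchor {anchor.symbol}: flank pool smaller than the "
                    f"neighborhood size {self.neighborhood_size}"
                )

    def species_clades(self) -> list[tuple[str, str]]:
        """Deterministic (species, clade) roster for ``n_species``."""
        names = list(self.clade_fractions)
        counts = {c: int(round(self.clade_fractions[c] * self.n_species)) for c in names}
        while sum(counts.values()) < self.n_species:
            counts[names[0]] += 1
        while sum(counts.values()) > self.n_species:
            counts[max(names, key=lambda c: counts[c])] -= 1
        roster = []
        i = 1
        for clade in names:
            for _ in range(counts[clade]):
                roster.append((f"{clade}_sp{i:02d}", clade))
                i += 1
        return roster


def discovery_config(seed: int, mutation_rate: float = 0.1) -> SimConfig:
    """Discovery-scale conditions: 18 species with enlarged tandem arrays so
    that exactly 100 planted IFN copies can be left unannotated while a
    training set of annotated copies remains."""
    anchors = (
        AnchorSpec(
            symbol="HACD4",
            flank_pool=default_anchors()[0].flank_pool,
            copy_number={"Mammalia": (6, 10), "Aves": (1, 1), "Reptilia": (4, 8)},
        ),
        default_anchors()[1],
        AnchorSpec(
            symbol="UBAP2",
            flank_pool=default_anchors()[2].flank_pool,
            copy_number={"Mammalia": (1, 1), "Aves": (3, 5), "Reptilia": (1, 1)},
        ),
    )
    return SimConfig(
        seed=seed,
        anchors=anchors,
        mutation_rate=mutation_rate,
        unannotated_count=100,
    )


def mutate_family(
    consensus: str, rate: float, n: int, seed: int | np.random.Generator
) -> list[str]:
    """n variants of the consensus, each residue substituted independently
    at the given rate by a uniformly drawn different residue."""
    if not 0 <= rate < 1:
        raise ConfigError(f"mutation rate {rate} outside [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    variants = []
    length = len(consensus)
    for _ in range(n):
        chars = list(consensus)
        hits = np.nonzero(rng.random(length) < rate)[0]
        for pos in hits:
            alternatives = AMINO_ACIDS.replace(chars[pos], "")
            chars[pos] = alternatives[rng.integers(len(alternatives))]
        variants.append("".join(chars))
    return variants


def back_translate(protein: str) -> str:
    """Deterministic nucleotide ORF: fixed codon per residue plus TAA."""
    return "".join(BACK_TRANSLATION[aa] for aa in protein) + "TAA"


def _random_protein(rng: np.random.Generator, length: int) -> str:
    body = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length - 1))
    return "M" + body


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


@dataclass
class _Gene:
    """Internal staging record before coordinates are laid down."""

    gene_id: str
    symbol: str
    descriptors: str
    is_ifn1: bool
    annotated: bool
    planted_locus: str
    aa_length: int
    strand: str
    protein: str | None = None  # filled only when sequences are materialised


@dataclass
class Pangenome:
    """In-memory simulation output."""

    config: SimConfig
    species: list[str]
    clades: dict[str, str]
    records: dict[str, list[GeneRecord]]
    sequences: dict[str, dict[str, str]]
    proteins: dict[str, str]
    truth: pd.DataFrame

    def all_records(self) -> list[GeneRecord]:
        return [r for species in self.species for r in self.records[species]]

    def records_with_unannotated(self) -> list[GeneRecord]:
        """Annotated records plus the unannotated IFN genes, as gene records.

        Locus analysis operates on annotated genes together with the IFN
        genes rediscovered by the classifier; this view supplies exactly
        that union from the truth table.
        """
        extra = [
            GeneRecord(
                species=row.species,
                chromosome=row.chromosome,
                start=int(row.start),
                end=int(row.end),
                strand=row.strand,
                symbol=row.symbol,
                descriptors=IFN_DESCRIPTION,
                is_ifn1=True,
            )
            for row in self.truth.itertuples(index=False)
            if row.is_ifn1 and not row.annotated
        ]
        return self.all_records() + extra

    def annotated_lookup(self) -> dict[str, bool]:
        lookup = {}
        for row in self.truth.itertuples(index=False):
            uid = f"{row.species}:{row.chromosome}:{row.start}-{row.end}:{row.symbol}"
            lookup[uid] = bool(row.annotated)
        return lookup

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for species in self.species:
            with open(out / f"{species}.gff3", "w") as handle:
                handle.write("##gff-version 3\n")
                chroms = self.sequences.get(species, {})
                for chrom, seq in chroms.items():
                    handle.write(f"##sequence-region {chrom} 1 {len(seq)}\n")
                for i, rec in enumerate(self.records[species]):
                    attrs = (
                        f"ID=gene{i:04d};gene={rec.symbol};"
                        f"description={rec.descriptors}"
                    )
                    handle.write(
                        f"{rec.chromosome}\tifnscope_sim\tgene\t{rec.start}\t{rec.end}"
                        f"\t.\t{rec.strand}\t.\t{attrs}\n"
                    )
            if species in self.sequences and self.sequences[species]:
                with open(out / f"{species}.fa", "w") as handle:
                    for chrom, seq in self.sequences[species].items():
                        handle.write(f">{chrom}\n")
                        for i in range(0, len(seq), 80):
                            handle.write(seq[i : i + 80] + "\n")
                with open(out / f"{species}.proteins.fa", "w") as handle:
                    for gene_id, protein in self.proteins.items():
                        if gene_id.startswith(species + ":"):
                            handle.write(f">{gene_id}\n{protein}\n")
        truth = self.truth.copy()
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)


IFN_DESCRIPTION = "type I interferon"
_DECOYS = (
    ("IFIT5", "interferon-induced protein with tetratricopeptide repeats"),
    ("IFNG", "interferon gamma type II cytokine"),
)


def simulate_pangenome(config: SimConfig, sequences: bool = True) -> Pangenome:
    """Generate the pangenome described by ``config``.

    With ``sequences=False`` only annotations and the truth table are
    produced (coordinates are identical to the full run for the same seed);
    this is the fast path for locus-analysis experiments that never touch
    nucleotide or protein sequence.
    """
    roster = config.species_clades()
    records: dict[str, list[GeneRecord]] = {}
    seqs: dict[str, dict[str, str]] = {}
    proteins: dict[str, str] = {}
    truth_rows: list[dict] = []
    dup_species_index = (
        int(np.random.default_rng([config.seed, 9999]).integers(config.n_species))
        if config.interchrom_dup
        else -1
    )

    all_ifn_keys: list[tuple[str, str]] = []  # (species, gene_id) regular IFN copies
    staged: dict[str, dict[str, list[_Gene]]] = {}

    for index, (species, clade) in enumerate(roster):
        rng_layout = np.random.default_rng([config.seed, index, 0])
        chrom_plan: dict[str, list[_Gene]] = {"chr1": []}
        gene_counter = 0

        def new_id() -> str:
            nonlocal gene_counter
            gene_counter += 1
            return f"{species}:g{gene_counter:04d}"

        def filler(prefix_locus: str = "") -> _Gene:
            return _Gene(
                gene_id=new_id(),
                symbol=f"{species}G{gene_counter:03d}",
                descriptors="hypothetical protein",
                is_ifn1=False,
                annotated=True,
                planted_locus=prefix_locus,
                aa_length=int(rng_layout.integers(120, 251)),
                strand="+-"[int(rng_layout.integers(2))],
            )

        def ifn(locus: str) -> _Gene:
            return _Gene(
                gene_id=new_id(),
                symbol=f"LOC{rng_layout.integers(100000, 999999)}",
                descriptors=IFN_DESCRIPTION,
                is_ifn1=True,
                annotated=True,
                planted_locus=locus,
                aa_length=len(config.family_consensus),
                strand="+-"[int(rng_layout.integers(2))],
            )

        # leading filler block with the decoy genes embedded
        block = [filler() for _ in range(config.fillers_per_block)]
        for symbol, description in _DECOYS:
            decoy = filler()
            decoy.symbol = symbol
            decoy.descriptors = description
            block.append(decoy)
        chrom_plan["chr1"].extend(block)

        for anchor in config.anchors:
            locus_genes: list[_Gene] = []
            lo, hi = anchor.copy_number.get(clade, (1, 1))
            copies = int(rng_layout.integers(lo, hi + 1))
            strand = "+-"[int(rng_layout.integers(2))]
            cluster = [ifn(anchor.symbol) for _ in range(copies)]
            for g in cluster:
                g.strand = strand  # tandem arrays are co-oriented
            # interrupt large arrays with one embedded non-IFN gene
            if copies >= 4:
                cut = int(rng_layout.integers(1, copies))
                cluster = cluster[:cut] + [filler(anchor.symbol)] + cluster[cut:]

            anchor_retained = rng_layout.random() < config.anchor_retention
            anchor_gene = _Gene(
                gene_id=new_id(),
                symbol=anchor.symbol,
                descriptors=f"{anchor.symbol} locus anchor protein",
                is_ifn1=False,
                annotated=anchor_retained,
                planted_locus=anchor.symbol,
                aa_length=int(rng_layout.integers(200, 401)),
                strand="+-"[int(rng_layout.integers(2))],
            )
            retained_flanks = [
                symbol
                for symbol in anchor.flank_pool
                if rng_layout.random() < anchor.retention
            ]
            others: list[_Gene] = [
                _Gene(
                    gene_id=new_id(),
                    symbol=symbol,
                    descriptors=f"{symbol} conserved neighborhood protein",
                    is_ifn1=False,
                    annotated=True,
                    planted_locus=anchor.symbol,
                    aa_length=int(rng_layout.integers(150, 301)),
                    strand="+-"[int(rng_layout.integers(2))],
                )
                for symbol in retained_flanks
            ] + [filler(anchor.symbol) for _ in range(config.private_per_locus)]
            order = rng_layout.permutation(len(others))
            left = [others[i] for i in order[0::2]]
            right = [others[i] for i in order[1::2]]
            # anchor sits immediately beside the cluster; other locus genes
            # spread outward on both sides
            if rng_layout.random() < 0.5:
                locus_genes = left[::-1] + [anchor_gene] + cluster + right
            else:
                locus_genes = left[::-1] + cluster + [anchor_gene] + right
            chrom_plan["chr1"].extend(locus_genes)
            chrom_plan["chr1"].extend(filler() for _ in range(config.fillers_per_block))
            all_ifn_keys.extend((species, g.gene_id) for g in cluster if g.is_ifn1)

        if index == dup_species_index:
            dup_flanks_left = [filler() for _ in range(5)]
            dup_flanks_right = [filler() for _ in range(5)]
            cog6 = filler()
            cog6.symbol, cog6.descriptors = "COG6", "COG6 novel flanking protein"
            lhfpl6 = filler()
            lhfpl6.symbol, lhfpl6.descriptors = "LHFPL6", "LHFPL6 novel flanking protein"
            dup = ifn("interchrom")
            chrom_plan["chr2"] = dup_flanks_left + [cog6, dup, lhfpl6] + dup_flanks_right

        staged[species] = chrom_plan
        records[species] = []
        seqs[species] = {}

    # choose which regular IFN copies go unannotated (global, seeded)
    rng_global = np.random.default_rng([config.seed, 7777])
    unannotated: set[tuple[str, str]] = set()
    if config.unannotated_count is not None:
        if config.unannotated_count > len(all_ifn_keys):
            raise ConfigError(
                f"cannot unannotate {config.unannotated_count} of "
                f"{len(all_ifn_keys)} planted IFN copies"
            )
        chosen = rng_global.choice(len(all_ifn_keys), size=config.unannotated_count, replace=False)
        unannotated = {all_ifn_keys[i] for i in chosen}
    else:
        for key in all_ifn_keys:
            if rng_global.random() < config.unannotated_fraction:
                unannotated.add(key)

    for index, (species, clade) in enumerate(roster):
        rng_seq = np.random.default_rng([config.seed, index, 1])
        rng_gap = np.random.default_rng([config.seed, index, 2])
        rng_dna = np.random.default_rng([config.seed, index, 3])
        for chrom, plan in staged[species].items():
            cursor = 0
            parts: list[str] = []
            for gene in plan:
                if (species, gene.gene_id) in unannotated:
                    gene.annotated = False
                gap = int(rng_gap.integers(150, 601))
                nt_length = 3 * gene.aa_length + 3
                start = cursor + gap + 1
                end = start + nt_length - 1
                cursor = end
                if sequences:
                    if gene.is_ifn1:
                        body = mutate_family(
                            config.family_consensus[1:], config.mutation_rate, 1, rng_seq
                        )[0]
                        gene.protein = "M" + body
                    else:
                        gene.protein = _random_protein(rng_seq, gene.aa_length)
                    orf = back_translate(gene.protein)
                    parts.append(_random_dna(rng_dna, gap))
                    parts.append(
                        orf if gene.strand == "+" else orf.translate(_COMPLEMENT)[::-1]
                    )
                    proteins[gene.gene_id] = gene.protein
                if gene.annotated:
                    records[species].append(
                        GeneRecord(
                            species=species,
                            chromosome=chrom,
                            start=start,
                            end=end,
                            strand=gene.strand,
                            symbol=gene.symbol,
                            descriptors=gene.descriptors,
                            is_ifn1=gene.is_ifn1,
                        )
                    )
                truth_rows.append(
                    {
                        "id": gene.gene_id,
                        "species": species,
                        "chromosome": chrom,
                        "start": start,
                        "end": end,
                        "strand": gene.strand,
                        "symbol": gene.symbol,
                        "is_ifn1": gene.is_ifn1,
                        "annotated": gene.annotated,
                        "planted_locus": gene.planted_locus,
                    }
                )
            tail_length = int(rng_gap.integers(150, 601))
            if sequences:
                seqs[species][chrom] = "".join(parts) + _random_dna(rng_dna, tail_length)

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "id", "species", "chromosome", "start", "end", "strand",
            "symbol", "is_ifn1", "annotated", "planted_locus",
        ],
    )
    return Pangenome(
        config=config,
        species=[s for s, _ in roster],
        clades=dict(roster),
        records=records,
        sequences=seqs,
        proteins=proteins,
        truth=truth,
    )


def emit_hits(
    pangenome: Pangenome, jitter: int = 30, seed: int = 0
) -> pd.DataFrame:
    """One pseudo translated-search hit per genomic IFN ORF.

    The hit covers a random internal in-frame window of the ORF, shrunk by
    up to ``jitter`` bp at each end but never past an internal Met on the
    5′ side, so outward extension recovers the planted ATG..stop interval
    exactly.  Minus-strand ORFs are reported with descending subject
    coordinates, matching the 12-column dialect.
    """
    rng = np.random.default_rng([pangenome.config.seed, 31337, seed])
    rows = []
    ifn_rows = pangenome.truth[pangenome.truth["is_ifn1"]]
    for row in ifn_rows.itertuples(index=False):
        protein = pangenome.proteins[row.id]
        L = len(protein)
        first_met = next((r for r in range(2, L + 1) if protein[r - 1] == "M"), None)
        cap5 = (first_met - 2) if first_met is not None else L
        max_codons = jitter // 3
        s5 = int(rng.integers(0, min(max_codons, cap5) + 1))
        s3 = int(rng.integers(0, max_codons + 1))
        if (L - 1) - s5 - s3 < 1:
            s5, s3 = 0, 0
        a = 4 + 3 * s5          # sense coordinate of window start
        b = 3 * L - 3 * s3      # sense coordinate of window end
        if row.strand == "+":
            sstart, send = row.start + a - 1, row.start + b - 1
        else:
            sstart, send = row.end - a + 1, row.end - b + 1
        aa_len = (b - a + 1) // 3
        rows.append(
            {
                "qseqid": "IFN_query",
                "sseqid": row.chromosome,
                "pident": 85.0,
                "length": aa_len,
                "mismatch": 0,
                "gapopen": 0,
                "qstart": 1,
                "qend": aa_len,
                "sstart": sstart,
                "send": send,
                "evalue": 1e-50,
                "bitscore": 200.0,
                "species": row.species,
            }
        )
    return pd.DataFrame(rows)


def write_hits(hits: pd.DataFrame, path: str) -> None:
    hits.drop(columns=["species"], errors="ignore").to_csv(
        path, sep="\t", index=False, header=False
    )


def build_training_set(
    pangenome: Pangenome,
    params=None,
    seed: int = 0,
    negative_ratio: float = 2.6,
):
    """Labelled APAAC dataset from the annotated genes of a pangenome.

    Positives are annotated IFN proteins; negatives are neighbourhood
    proteins — composition-preserving shuffles of filler proteins by
    default, or variants of an unrelated family when the config says so —
    subsampled to ``negative_ratio`` negatives per positive.
    """
    from .apaac import ApaacParams, featurize
    from .scope_classifier import LabeledDataset

    params = params or ApaacParams()
    rng = np.random.default_rng([pangenome.config.seed, 555, seed])
    annotated = pangenome.truth[pangenome.truth["annotated"]]
    pos_ids = list(annotated[annotated["is_ifn1"]]["id"])
    neg_pool = list(annotated[~annotated["is_ifn1"]]["id"])
    n_neg = min(len(neg_pool), int(round(negative_ratio * len(pos_ids))))
    neg_ids = [neg_pool[i] for i in rng.choice(len(neg_pool), size=n_neg, replace=False)]

    sequences: dict[str, str] = {i: pangenome.proteins[i] for i in pos_ids}
    if pangenome.config.negative_source == "unrelated-family":
        variants = mutate_family(
            UNRELATED_CONSENSUS, pangenome.config.mutation_rate, len(neg_ids), rng
        )
        for neg_id, variant in zip(neg_ids, variants):
            sequences[neg_id] = variant
    else:
        for neg_id in neg_ids:
            chars = list(pangenome.proteins[neg_id])
            rng.shuffle(chars)
            sequences[neg_id] = "".join(chars)

    features = featurize(sequences, params)
    labels = np.array([i in set(pos_ids) for i in features.index])
    return LabeledDataset(features.to_numpy(), labels, tuple(features.index))
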