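"""Candidate ORF construction from translated-homology hits.

Translated searches (tblastn and kin) report where a known IFN protein
aligns on a genome, but the aligned window rarely covers the whole coding
region.  This module walks outward from each hit, in the hit's reading
frame, to the nearest in-frame start codon (ATG) upstream and the nearest
in-frame stop codon downstream, yielding complete ATG..stop candidate
coding intervals that are then translated and screened against already
annotated IFN genes.

Amniote type I IFNs are treated as intronless, so a candidate is a single
genomic interval; no splice modelling is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .annotation_io import GeneRecord, gene_position
from .errors import (
    AlphabetError,
    FrameError,
    HitParseError,
    InternalStopError,
    SequenceLookupError,
)

STOP_CODONS = {"TAA", "TAG", "TGA"}
_DNA = set("ACGT")


@dataclass(frozen=True)
class HomologyHit:
    """One row of a 12-column tabular search result, coordinates ascending."""

    query_id: str
    subject_chromosome: str
    subject_start: int
    subject_end: int
    strand: str
    evalue: float
    frame: int | None = None

    def __post_init__(self) -> None:
        if self.subject_start > self.subject_end:
            raise ValueError("subject coordinates must be normalized ascending")
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")


@dataclass(frozen=True)
class CandidateORF:
    """A complete start-to-stop coding interval on the genome.

    ``nucleotide`` is the coding-strand sequence (ATG..stop); ``protein``
    drops the terminal stop.  Coordinates are 1-based inclusive on the
    forward strand regardless of ``strand``.
    """

    chromosome: str
    start: int
    end: int
    strand: str
    nucleotide: str
    protein: str
    name: str = ""
    source_query: str = ""
    evalue: float = 0.0

    def validate(self) -> None:
        assert len(self.nucleotide) % 3 == 0
        assert self.nucleotide.startswith("ATG")
        assert self.nucleotide[-3:] in STOP_CODONS
        assert len(self.protein) == len(self.nucleotide) // 3 - 1
        assert "*" not in self.protein
        assert self.end - self.start + 1 == len(self.nucleotide)


def parse_hits(path: str) -> list[HomologyHit]:
    """Read a 12-column tab-separated hit file (BLAST outfmt-6 dialect).

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore.  Subject coordinates descending signal a
    minus-strand hit and are normalized ascending.
    """
    hits: list[HomologyHit] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise HitParseError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(fields)}"
                )
            try:
                sstart, send = int(fields[8]), int(fields[9])
                evalue = float(fields[10])
            except ValueError as exc:
                raise HitParseError(f"{path}:{lineno}: {exc}") from exc
            strand = "+" if sstart <= send else "-"
            lo, hi = min(sstart, send), max(sstart, send)
            hits.append(
                HomologyHit(
                    query_id=fields[0],
                    subject_chromosome=fields[1],
                    subject_start=lo,
                    subject_end=hi,
                    strand=strand,
                    evalue=evalue,
                )
            )
    return hits


def translate(nucleotide: str) -> str:
    """Standard-code translation; the terminal stop codon is dropped.

    Raises on length not divisible by 3, non-ACGT symbols, and in-frame
    internal stops.
    """
    if len(nucleotide) % 3 != 0:
        raise FrameError(f"length {len(nucleotide)} not divisible by 3")
    bad = set(nucleotide.upper()) - _DNA
    if bad:
        raise AlphabetError(f"non-ACGT symbols: {sorted(bad)}")
    protein = str(Seq(nucleotide.upper()).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        raise InternalStopError(
            f"internal stop at codon {protein.index('*') + 1}"
        )
    return protein


def _sequence(genome: Mapping[str, str], chromosome: str) -> str:
    try:
        seq = genome[chromosome]
    except KeyError as exc:
        raise SequenceLookupError(f"chromosome {chromosome!r} not in sequence store") from exc
    return str(seq).upper()


def _scan_plus(seq: str, start0: int, end0: int, max_extension: int):
    """Find (atg0, stop_end0) on the forward strand or None.

    ``start0``/``end0`` bound the hit half-open on 0-based coordinates.
    The upstream walk starts at the codon immediately before the hit's 5′
    boundary and steps outward; the first in-frame ATG wins, an in-frame
    stop or an ambiguity code aborts the walk.  Codons inside the aligned
    span are never start candidates — the alignment is assumed to lie
    downstream of the true start.
    """
    atg0 = None
    steps = max_extension // 3
    for k in range(1, steps + 1):
        p = start0 - 3 * k
        if p < 0:
            break
        codon = seq[p : p + 3]
        if set(codon) - _DNA:
            return None
        if codon == "ATG":
            atg0 = p
            break
        if codon in STOP_CODONS:
            return None
    if atg0 is None:
        return None

    stop_end0 = None
    for k in range(0, steps + 1):
        q = end0 + 3 * k
        if q + 3 > len(seq):
            return None
        codon = seq[q : q + 3]
        if set(codon) - _DNA:
            return None
        if codon in STOP_CODONS:
            stop_end0 = q + 3
            break
    if stop_end0 is None:
        return None
    return atg0, stop_end0


def extend_to_orf(
    hit: HomologyHit,
    genome: Mapping[str, str],
    max_extension: int = 6000,
) -> CandidateORF | None:
    """Extend a hit to a complete ATG..stop ORF in the hit's frame.

    Returns None when no in-frame ATG or stop lies within ``max_extension``
    bp of the hit in the respective direction, when an in-frame stop blocks
    the upstream walk, or when the scanned window contains ambiguity codes.
    """
    seq = _sequence(genome, hit.subject_chromosome)
    span = hit.subject_end - hit.subject_start + 1
    if span % 3 != 0:
        raise FrameError(
            f"hit span {span} bp is not a whole number of codons"
        )
    if hit.subject_end > len(seq):
        raise SequenceLookupError(
            f"hit end {hit.subject_end} beyond {hit.subject_chromosome} length {len(seq)}"
        )

    if hit.strand == "+":
        found = _scan_plus(seq, hit.subject_start - 1, hit.subject_end, max_extension)
        if found is None:
            return None
        atg0, stop_end0 = found
        start, end = atg0 + 1, stop_end0
        nucleotide = seq[atg0:stop_end0]
    else:
        rc = str(Seq(seq).reverse_complement())
        length = len(seq)
        # genomic [s, e] maps to [L - e + 1, L - s + 1] on the reverse complement
        rc_start0 = length - hit.subject_end
        rc_end0 = length - hit.subject_start + 1
        found = _scan_plus(rc, rc_start0, rc_end0, max_extension)
        if found is None:
            return None
        atg0, stop_end0 = found
        start, end = length - stop_end0 + 1, length - atg0
        nucleotide = rc[atg0:stop_end0]

    try:
        protein = translate(nucleotide)
    except InternalStopError:
        return None
    orf = CandidateORF(
        chromosome=hit.subject_chromosome,
        start=start,
        end=end,
        strand=hit.strand,
        nucleotide=nucleotide,
        protein=protein,
        source_query=hit.query_id,
        evalue=hit.evalue,
    )
    orf.validate()
    return orf


def screen_candidates(
    orfs: Iterable[CandidateORF],
    annotated: Sequence[GeneRecord],
    species: str,
) -> list[CandidateORF]:
    """Drop candidates overlapping annotated IFN genes; dedupe; name survivors.

    Any overlap of ≥ 1 bp with an annotated type I IFN interval on the same
    chromosome removes the candidate (it is already known).  Candidates with
    identical (chromosome, start, end, strand) collapse to one.  Survivors
    are named ``{species}_{chromosome}_POS{position}`` with the midpoint
    position of the candidate interval.
    """
    ifn_intervals: dict[str, list[tuple[int, int]]] = {}
    for record in annotated:
        if record.is_ifn1:
            ifn_intervals.setdefault(record.chromosome, []).append((record.start, record.end))

    survivors: list[CandidateORF] = []
    seen: set[tuple[str, int, int, str]] = set()
    for orf in orfs:
        key = (orf.chromosome, orf.start, orf.end, orf.strand)
        if key in seen:
            continue
        seen.add(key)
        overlaps = any(
            orf.start <= e and orf.end >= s
            for s, e in ifn_intervals.get(orf.chromosome, [])
        )
        if overlaps:
            continue
        name = f"{species}_{orf.chromosome}_POS{gene_position(orf.start, orf.end)}"
        survivors.append(
            CandidateORF(
                chromosome=orf.chromosome,
                start=orf.start,
                end=orf.end,
                strand=orf.strand,
                nucleotide=orf.nucleotide,
                protein=orf.protein,
                name=name,
                source_query=orf.source_query,
                evalue=orf.evalue,
            )
        )
    return survivors


def tblastn_command(
    query_fasta: str, database: str, out_path: str, evalue: float = 1e-5
) -> list[str]:
    """Command line for the optional external translated search.

    The search itself is never re-implemented here; tests run on
    pre-computed tabular files, so the external tool is not a dependency.
    """
    return [
        "tblastn",
        "-query", query_fasta,
        "-db", database,
        "-out", out_path,
        "-evalue", str(evalue),
        "-outfmt", "6",
    ]


def run_tblastn(
    query_fasta: str, database: str, out_path: str, evalue: float = 1e-5
) -> None:
    """Invoke the external translated search (optional convenience)."""
    import subprocess

    subprocess.run(
        tblastn_command(query_fasta, database, out_path, evalue), check=True
    )


def candidates_to_frame(orfs: Sequence[CandidateORF]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "name": o.name,
                "chromosome": o.chromosome,
                "start": o.start,
                "end": o.end,
                "strand": o.strand,
                "source_query": o.source_query,
                "evalue": o.evalue,
                "protein": o.protein,
            }
            for o in orfs
        ],
        columns=["name", "chromosome", "start", "end", "strand", "source_query", "evalue", "protein"],
    )


def write_candidates(orfs: Sequence[CandidateORF], out_prefix: str) -> None:
    """Write protein FASTA, nucleotide FASTA and a TSV manifest."""
    with open(f"{out_prefix}.protein.fa", "w") as handle:
        for o in orfs:
            handle.write(f">{o.name}\n{o.protein}\n")
    with open(f"{out_prefix}.nucleotide.fa", "w") as handle:
        for o in orfs:
            handle.write(f">{o.name}\n{o.nucleotide}\n")
    candidates_to_frame(orfs).drop(columns=["protein"]).to_csv(
        f"{out_prefix}.manifest.tsv", sep="\t", index=False
    )
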