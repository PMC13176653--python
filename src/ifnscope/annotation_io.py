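"""Gene-level annotation handling.

Parses per-species GFF3 files into :class:`GeneRecord` lists, applies the
keyword filters that recognise annotated type I interferon (IFN) genes,
computes midpoint gene positions, and extracts the 10 nearest non-IFN
neighbours of a focal gene — the "neighbourhood" unit every downstream
synteny computation is built on.

Coordinates follow the GFF3 convention (1-based, inclusive) everywhere.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .errors import CoordinateOrderError, GffParseError

PSEUDOGENE = "pseudogene"
LOW_QUALITY = "low_quality_protein"

#: stems matched case-insensitively against the concatenated descriptor text;
#: "induc" covers induced/inducible, "stimulat" covers stimulated/stimulator
EXCLUDE_STEMS = ("type ii", "type iii", "factor", "induc", "stimulat")


def gene_position(start: int, end: int) -> int:
    """Midpoint of a gene interval, rounded half-up to an integer (bp).

    This is the single notion of "gene position" used for neighbourhoods,
    locus assignment and candidate naming.
    """
    if start > end:
        raise CoordinateOrderError(f"start {start} > end {end}")
    if start < 1:
        raise CoordinateOrderError(f"coordinates must be positive, got start={start}")
    return (start + end + 1) // 2


@dataclass(frozen=True)
class GeneRecord:
    """One gene-level annotation row.

    ``descriptors`` concatenates the free-text product/description/
    abbreviation attributes; ``flags`` is drawn from {pseudogene,
    low_quality_protein}; ``is_ifn1`` marks genes recognised as annotated
    type I IFNs.
    """

    species: str
    chromosome: str
    start: int
    end: int
    strand: str
    symbol: str
    descriptors: str = ""
    flags: frozenset[str] = field(default_factory=frozenset)
    is_ifn1: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise CoordinateOrderError(
                f"{self.symbol}: start {self.start} > end {self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.symbol}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def position(self) -> int:
        return gene_position(self.start, self.end)

    @property
    def uid(self) -> str:
        return f"{self.species}:{self.chromosome}:{self.start}-{self.end}:{self.symbol}"


@dataclass(frozen=True)
class Neighborhood:
    """A focal gene plus its ``n`` nearest non-IFN neighbours, nearest first.

    ``truncated`` is set when the chromosome holds fewer than ``n`` non-IFN
    genes.
    """

    focal: GeneRecord
    neighbors: tuple[GeneRecord, ...]
    truncated: bool = False

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(r.symbol for r in self.neighbors)


def is_type1_ifn(descriptors: str, flags: Iterable[str] = ()) -> bool:
    """Keyword test for an annotated type I IFN gene.

    Keeps a record iff the descriptor text contains (case-insensitively)
    "type i" AND ("interferon" OR "ifn"), does not contain any exclusion
    stem (type ii/iii, factor, induc*, stimulat*), and the record is not
    flagged as a pseudogene or low-quality protein.
    """
    text = descriptors.lower()
    if "type i" not in text:
        return False
    if "interferon" not in text and "ifn" not in text:
        return False
    if any(stem in text for stem in EXCLUDE_STEMS):
        return False
    if PSEUDOGENE in flags or LOW_QUALITY in flags:
        return False
    return True


def filter_type1_ifn(records: Sequence[GeneRecord]) -> list[GeneRecord]:
    """Subset of ``records`` recognised as annotated type I IFN genes."""
    return [r for r in records if is_type1_ifn(r.descriptors, r.flags)]


def annotate_ifn_labels(records: Sequence[GeneRecord]) -> list[GeneRecord]:
    """Return copies of ``records`` with ``is_ifn1`` set from the keyword filter."""
    return [replace(r, is_ifn1=is_type1_ifn(r.descriptors, r.flags)) for r in records]


def extract_neighborhood(
    focal: GeneRecord,
    chromosome_records: Sequence[GeneRecord],
    n: int = 10,
) -> Neighborhood:
    """The ``n`` non-IFN genes nearest the focal gene's position.

    Distance is |position(neighbor) − position(focal)|; ties break on the
    smaller start coordinate, then lexicographic symbol, so output order is
    deterministic.  The focal record itself is never its own neighbour.
    """
    fpos = focal.position
    candidates = [
        r
        for r in chromosome_records
        if not r.is_ifn1 and r.chromosome == focal.chromosome and r.uid != focal.uid
    ]
    candidates.sort(key=lambda r: (abs(r.position - fpos), r.start, r.symbol))
    chosen = tuple(candidates[:n])
    return Neighborhood(focal=focal, neighbors=chosen, truncated=len(chosen) < n)


# ---------------------------------------------------------------------------
# gene-name revision
# ---------------------------------------------------------------------------

def _slug(text: str) -> str:
    slug = re.sub(r"[^A-Za-z0-9]+", "_", text.strip()).strip("_")
    return slug.upper() or "UNNAMED"


@dataclass
class NameReviser:
    """Pluggable gene-symbol revision hook.

    Public annotation databases name the same gene inconsistently across
    species; the exact harmonisation applied upstream of this pipeline is
    database-specific, so revision is exposed as a mapping table plus a
    default rule: prefer the gene-symbol attribute, else the abbreviation,
    else a slug of the product string.
    """

    mapping: Mapping[str, str] = field(default_factory=dict)
    rule: Callable[[dict], str] | None = None

    def revise(self, attributes: dict) -> str:
        if self.rule is not None:
            symbol = self.rule(attributes)
        else:
            symbol = (
                _first(attributes, "gene", "Name")
                or _first(attributes, "gene_abbr", "abbreviation")
                or _slug(_first(attributes, "product", "description") or "")
            )
        return self.mapping.get(symbol, symbol)


def _first(attributes: dict, *keys: str) -> str | None:
    for key in keys:
        value = attributes.get(key)
        if value:
            return value[0] if isinstance(value, (list, tuple)) else value
    return None


# ---------------------------------------------------------------------------
# GFF3 ingestion / TSV round trip
# ---------------------------------------------------------------------------

_GENE_TYPES = {"gene", "pseudogene"}


def read_gff3(
    path: str,
    species: str,
    reviser: NameReviser | None = None,
    unplaced: Iterable[str] = (),
) -> list[GeneRecord]:
    """Parse gene-level features of a GFF3 file into labelled GeneRecords.

    Pseudogene features (or ``pseudo=true`` attributes) set the pseudogene
    flag; a "LOW QUALITY PROTEIN" marker in the free text sets the
    low-quality flag.  Sequence IDs listed in ``unplaced`` are dropped,
    mirroring the exclusion of unplaced genome scaffolds from locus
    analysis.  Type I IFN labels are applied on the way out.
    """
    import gffutils

    reviser = reviser or NameReviser()
    unplaced = set(unplaced)
    try:
        db = gffutils.create_db(
            path,
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises bare ValueError on bad input
        raise GffParseError(f"{path}: {exc}") from exc

    records: list[GeneRecord] = []
    for feature in db.all_features():
        if feature.featuretype not in _GENE_TYPES:
            continue
        if feature.seqid in unplaced:
            continue
        attrs = dict(feature.attributes)
        flags = set()
        if feature.featuretype == "pseudogene" or _first(attrs, "pseudo") in {"true", "True"}:
            flags.add(PSEUDOGENE)
        descriptors = " ".join(
            filter(None, (_first(attrs, "product"), _first(attrs, "description"), _first(attrs, "gene_abbr")))
        )
        if "low quality protein" in descriptors.lower():
            flags.add(LOW_QUALITY)
        records.append(
            GeneRecord(
                species=species,
                chromosome=feature.seqid,
                start=feature.start,
                end=feature.end,
                strand=feature.strand if feature.strand in {"+", "-"} else "+",
                symbol=reviser.revise(attrs),
                descriptors=descriptors,
                flags=frozenset(flags),
            )
        )
    return annotate_ifn_labels(records)


_TSV_COLUMNS = [
    "species", "chromosome", "start", "end", "strand",
    "symbol", "is_ifn1", "flags", "position", "descriptors",
]


def records_to_frame(records: Sequence[GeneRecord]) -> pd.DataFrame:
    rows = [
        {
            "species": r.species,
            "chromosome": r.chromosome,
            "start": r.start,
            "end": r.end,
            "strand": r.strand,
            "symbol": r.symbol,
            "is_ifn1": r.is_ifn1,
            "flags": ",".join(sorted(r.flags)),
            "position": r.position,
            "descriptors": r.descriptors,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=_TSV_COLUMNS)


def write_annotation_tsv(records: Sequence[GeneRecord], path: str) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path: str) -> list[GeneRecord]:
    frame = pd.read_csv(path, sep="\t", keep_default_na=False, dtype={"flags": str})
    records = []
    for row in frame.itertuples(index=False):
        flags = frozenset(f for f in str(row.flags).split(",") if f)
        records.append(
            GeneRecord(
                species=str(row.species),
                chromosome=str(row.chromosome),
                start=int(row.start),
                end=int(row.end),
                strand=str(row.strand),
                symbol=str(row.symbol),
                descriptors=str(getattr(row, "descriptors", "")),
                flags=flags,
                is_ifn1=bool(row.is_ifn1),
            )
        )
    return records
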