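"""Conserved-locus detection by knowledge-graph degree centrality.

Tandemly arrayed IFN genes are merged into clusters; each cluster's 10
nearest non-IFN neighbours form a "gene chain"; chains from every species
are merged into one graph where neighbour genes with the same symbol are a
single node.  A symbol's degree then counts how many IFN clusters — across
all species — it flanks, so recurrent flanking genes (the conserved loci)
surface as high-degree hubs.  Loci are extracted greedily: take the
maximum-degree symbol while its degree exceeds a threshold (default 15,
strict), delete every chain containing it, repeat.  Finally each IFN gene
is assigned to the conserved locus found in its own neighbourhood, or to
the "exception" category — the signature of interchromosomal duplications.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .annotation_io import GeneRecord, Neighborhood, extract_neighborhood, gene_position
from .errors import EmptySummaryError

EXCEPTION = "exception"


@dataclass(frozen=True)
class IfnCluster:
    """A maximal run of IFN genes with no intervening non-IFN gene."""

    species: str
    chromosome: str
    genes: tuple[GeneRecord, ...]

    @property
    def start(self) -> int:
        return min(g.start for g in self.genes)

    @property
    def end(self) -> int:
        return max(g.end for g in self.genes)

    @property
    def position(self) -> int:
        return gene_position(self.start, self.end)


@dataclass(frozen=True)
class GeneChain:
    """One IFN cluster plus the symbols of its neighbourhood genes."""

    chain_id: str
    species: str
    cluster: IfnCluster
    neighbor_symbols: tuple[str, ...]
    neighbor_positions: tuple[int, ...]


@dataclass(frozen=True)
class LocusCall:
    locus_symbol: str
    degree_at_extraction: int
    extraction_rank: int


@dataclass(frozen=True)
class LocusAssignment:
    ifn_gene: GeneRecord
    locus: str
    distance: int | None = None
    annotated: bool = True


def merge_ifn_clusters(genes: Sequence[GeneRecord]) -> list[IfnCluster]:
    """Group IFN genes into clusters per (species, chromosome).

    IFN genes are merged whenever no non-IFN gene lies between them in
    positional order; singleton IFNs form singleton clusters.
    """
    clusters: list[IfnCluster] = []
    keyed = sorted(genes, key=lambda g: (g.species, g.chromosome, g.position, g.start))
    for (species, chromosome), group in itertools.groupby(
        keyed, key=lambda g: (g.species, g.chromosome)
    ):
        run: list[GeneRecord] = []
        for gene in group:
            if gene.is_ifn1:
                run.append(gene)
            elif run:
                clusters.append(IfnCluster(species, chromosome, tuple(run)))
                run = []
        if run:
            clusters.append(IfnCluster(species, chromosome, tuple(run)))
    return clusters


def _cluster_neighborhood(
    cluster: IfnCluster, chromosome_records: Sequence[GeneRecord], n_neighbors: int
) -> Neighborhood:
    focal = GeneRecord(
        species=cluster.species,
        chromosome=cluster.chromosome,
        start=cluster.start,
        end=cluster.end,
        strand=cluster.genes[0].strand,
        symbol=f"cluster:{cluster.position}",
        is_ifn1=True,
    )
    return extract_neighborhood(focal, chromosome_records, n=n_neighbors)


def build_chains(
    genes: Sequence[GeneRecord], n_neighbors: int = 10
) -> list[GeneChain]:
    """One chain per IFN cluster, with the n nearest non-IFN gene symbols.

    Neighbour distance is measured from the midpoint of the cluster's
    spanning interval, so tandem arrays contribute a single chain and do
    not inflate the degree of their flanking genes.
    """
    by_chrom: dict[tuple[str, str], list[GeneRecord]] = {}
    for gene in genes:
        by_chrom.setdefault((gene.species, gene.chromosome), []).append(gene)
    chains: list[GeneChain] = []
    for cluster in merge_ifn_clusters(genes):
        records = by_chrom[(cluster.species, cluster.chromosome)]
        hood = _cluster_neighborhood(cluster, records, n_neighbors)
        chains.append(
            GeneChain(
                chain_id=f"{cluster.species}:{cluster.chromosome}:{cluster.position}",
                species=cluster.species,
                cluster=cluster,
                neighbor_symbols=hood.symbols,
                neighbor_positions=tuple(r.position for r in hood.neighbors),
            )
        )
    return chains


def build_graph(chains: Sequence[GeneChain]) -> nx.Graph:
    """Merged knowledge graph: one node per chain, one per distinct symbol.

    Edges link a chain's IFN-cluster node to each of its neighbour symbols,
    so a symbol node's degree equals the number of distinct IFN clusters it
    flanks.  Genes on no chain are absent by construction.
    """
    graph = nx.Graph()
    for chain in chains:
        graph.add_node(chain.chain_id, kind="chain", chain=chain)
        for symbol in set(chain.neighbor_symbols):
            if not graph.has_node(symbol):
                graph.add_node(symbol, kind="symbol")
            graph.add_edge(chain.chain_id, symbol)
    return graph


def extract_conserved_loci(
    graph: nx.Graph, min_degree: int = 15, degree_mode: str = "chains"
) -> list[LocusCall]:
    """Iterative maximum-degree extraction of conserved locus symbols.

    Each round takes the highest-degree symbol node (ties broken
    lexicographically); if its degree is strictly greater than
    ``min_degree`` it is emitted and every chain containing it is deleted
    (with any symbol nodes thereby orphaned); otherwise the loop ends.

    ``degree_mode`` chooses what a symbol's degree counts: adjacent IFN
    clusters ("chains", the default) or distinct species among them
    ("species") — the two differ when one species contributes several
    chains flanking the same symbol.
    """
    if degree_mode not in {"chains", "species"}:
        raise ValueError(f"unknown degree mode {degree_mode!r}")

    def _degree(g: nx.Graph, symbol) -> int:
        if degree_mode == "chains":
            return g.degree(symbol)
        return len({g.nodes[c]["chain"].species for c in g.neighbors(symbol)})

    work = graph.copy()
    calls: list[LocusCall] = []
    while True:
        symbols = [n for n, data in work.nodes(data=True) if data.get("kind") == "symbol"]
        if not symbols:
            break
        best = min(symbols, key=lambda s: (-_degree(work, s), s))
        degree = _degree(work, best)
        if degree <= min_degree:
            break
        calls.append(LocusCall(best, degree, len(calls) + 1))
        doomed_chains = list(work.neighbors(best))
        work.remove_nodes_from(doomed_chains)
        work.remove_node(best)
        orphans = [
            n
            for n, data in work.nodes(data=True)
            if data.get("kind") == "symbol" and work.degree(n) == 0
        ]
        work.remove_nodes_from(orphans)
    return calls


def assign_loci(
    ifn_genes: Sequence[GeneRecord],
    loci: Sequence[LocusCall],
    all_genes: Sequence[GeneRecord],
    n_neighbors: int = 10,
    annotated_lookup: Mapping[str, bool] | None = None,
) -> list[LocusAssignment]:
    """Assign every IFN gene to a conserved locus or the exception category.

    A gene is assigned to a locus iff the locus symbol appears in the
    gene's own 10-gene neighbourhood; when several qualify the nearest (by
    midpoint distance) wins.  ``annotated_lookup`` optionally maps gene
    uids to their annotated/unannotated status for downstream summaries.
    """
    locus_symbols = {call.locus_symbol for call in loci}
    by_chrom: dict[tuple[str, str], list[GeneRecord]] = {}
    for gene in all_genes:
        by_chrom.setdefault((gene.species, gene.chromosome), []).append(gene)
    assignments: list[LocusAssignment] = []
    for gene in ifn_genes:
        records = by_chrom.get((gene.species, gene.chromosome), [])
        hood = extract_neighborhood(gene, records, n=n_neighbors)
        candidates = [
            (abs(r.position - gene.position), r.symbol)
            for r in hood.neighbors
            if r.symbol in locus_symbols
        ]
        annotated = True
        if annotated_lookup is not None:
            annotated = annotated_lookup.get(gene.uid, True)
        if candidates:
            distance, symbol = min(candidates)
            assignments.append(LocusAssignment(gene, symbol, distance, annotated))
        else:
            assignments.append(LocusAssignment(gene, EXCEPTION, None, annotated))
    return assignments


def locus_summary(
    assignments: Sequence[LocusAssignment],
) -> tuple[pd.DataFrame, float]:
    """Per-locus annotated/unannotated counts and the conserved-locus share.

    Returns the count table plus 100 × (total − exceptions) / total rounded
    to one decimal.
    """
    if not assignments:
        raise EmptySummaryError("no locus assignments to summarize")
    rows: dict[str, dict[str, int]] = {}
    for a in assignments:
        bucket = rows.setdefault(a.locus, {"annotated": 0, "unannotated": 0})
        bucket["annotated" if a.annotated else "unannotated"] += 1
    frame = (
        pd.DataFrame.from_dict(rows, orient="index")
        .rename_axis("locus")
        .reset_index()
    )
    frame["total"] = frame["annotated"] + frame["unannotated"]
    total = int(frame["total"].sum())
    exceptions = int(frame.loc[frame["locus"] == EXCEPTION, "total"].sum())
    percent = round(100.0 * (total - exceptions) / total, 1)
    return frame, percent


def run_locus_analysis(
    genes: Sequence[GeneRecord],
    min_degree: int = 15,
    n_neighbors: int = 10,
    annotated_lookup: Mapping[str, bool] | None = None,
) -> tuple[list[LocusCall], list[LocusAssignment], pd.DataFrame, float]:
    """Chains → graph → loci → assignments → summary, in one call."""
    chains = build_chains(genes, n_neighbors=n_neighbors)
    graph = build_graph(chains)
    loci = extract_conserved_loci(graph, min_degree=min_degree)
    ifn_genes = [g for g in genes if g.is_ifn1]
    assignments = assign_loci(
        ifn_genes, loci, genes, n_neighbors=n_neighbors, annotated_lookup=annotated_lookup
    )
    summary, percent = locus_summary(assignments) if assignments else (pd.DataFrame(), float("nan"))
    return loci, assignments, summary, percent
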