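"""Cluster merging, chain/graph construction, locus extraction and assignment."""

import numpy as np
import pytest

from ifnscope import gene_grade as gg
from ifnscope.annotation_io import GeneRecord
from ifnscope.errors import EmptySummaryError


def _gene(symbol, pos, is_ifn1=False, species="sp", chrom="chr1", width=10):
    return GeneRecord(
        species=species,
        chromosome=chrom,
        start=pos - width // 2,
        end=pos + width // 2,
        strand="+",
        symbol=symbol,
        is_ifn1=is_ifn1,
    )


def _layout(pattern, species="sp", spacing=1000):
    """Build records from a string like 'N I I N': I = IFN, N = non-IFN."""
    records = []
    for i, token in enumerate(pattern.split()):
        pos = 1000 + i * spacing
        records.append(
            _gene(
                f"IFN{i}" if token == "I" else f"G{i}",
                pos,
                is_ifn1=(token == "I"),
                species=species,
            )
        )
    return records


class TestMergeClusters:
    def test_tandem_array_is_one_cluster(self):
        clusters = gg.merge_ifn_clusters(_layout("N I I I N"))
        assert len(clusters) == 1 and len(clusters[0].genes) == 3

    def test_interrupting_gene_splits_cluster(self):
        clusters = gg.merge_ifn_clusters(_layout("I N I"))
        assert [len(c.genes) for c in clusters] == [1, 1]

    def test_twelve_gene_array_with_one_embedded_interrupter(self):
        pattern = "N " + "I " * 5 + "N " + "I " * 7 + "N"
        clusters = gg.merge_ifn_clusters(_layout(pattern))
        assert sorted(len(c.genes) for c in clusters) == [5, 7]

    def test_clusters_never_span_chromosomes(self):
        a = _layout("I I", species="sp")
        b = [_gene("IFNX", 1000, is_ifn1=True, chrom="chr2")]
        clusters = gg.merge_ifn_clusters(a + b)
        assert len(clusters) == 2


class TestBuildChains:
    def test_singleton_chain_equals_gene_neighborhood(self):
        records = _layout("N N I N N")
        (chain,) = gg.build_chains(records, n_neighbors=4)
        assert set(chain.neighbor_symbols) == {"G0", "G1", "G3", "G4"}

    def test_neighbors_measured_from_cluster_midpoint(self):
        # cluster spans positions 2000..4000, midpoint 3000
        records = _layout("N I I I N N N")
        (chain,) = gg.build_chains(records, n_neighbors=3)
        midpoint = chain.cluster.position
        expected = sorted(
            (r for r in records if not r.is_ifn1),
            key=lambda r: (abs(r.position - midpoint), r.start, r.symbol),
        )[:3]
        assert chain.neighbor_symbols == tuple(r.symbol for r in expected)

    def test_one_chain_per_cluster(self):
        records = _layout("I N I N I")
        assert len(gg.build_chains(records)) == 3


class TestBuildGraph:
    def _chains_sharing(self, n, shared="HACD4"):
        chains = []
        for i in range(n):
            records = _layout("N I N", species=f"sp{i}")
            records[0] = _gene(shared, 1000, species=f"sp{i}")
            chains.extend(gg.build_chains(records, n_neighbors=2))
        return chains

    def test_shared_symbol_degree_counts_chains(self):
        graph = gg.build_graph(self._chains_sharing(20))
        assert graph.degree("HACD4") == 20

    def test_private_symbols_have_degree_one_and_disjoint_chains_disconnect(self):
        import networkx as nx

        chains = self._chains_sharing(2, shared="X")
        # rename the shared symbol apart so the two chains share nothing
        graph = gg.build_graph(
            [
                gg.GeneChain(c.chain_id, c.species, c.cluster,
                             tuple(f"{c.species}_{s}" for s in c.neighbor_symbols),
                             c.neighbor_positions)
                for c in chains
            ]
        )
        symbol_degrees = {
            n: d for n, d in graph.degree() if graph.nodes[n].get("kind") == "symbol"
        }
        assert set(symbol_degrees.values()) == {1}
        assert nx.number_connected_components(graph) == 2

    def test_degrees_match_brute_force_on_random_chain_sets(self, rng):
        """Degree oracle: count chains whose symbol set contains the node."""
        for _ in range(20):
            n_chains = int(rng.integers(2, 51))
            chains = []
            for i in range(n_chains):
                symbols = tuple(
                    f"S{j}" for j in rng.choice(60, size=10, replace=False)
                )
                cluster = gg.IfnCluster(f"sp{i}", "chr1", (_gene("I", 1000, True, species=f"sp{i}"),))
                chains.append(gg.GeneChain(f"c{i}", f"sp{i}", cluster, symbols, tuple([0] * 10)))
            graph = gg.build_graph(chains)
            for node, data in graph.nodes(data=True):
                if data.get("kind") != "symbol":
                    continue
                brute = sum(node in c.neighbor_symbols for c in chains)
                assert graph.degree(node) == brute


def _synthetic_chains(spec):
    """spec: list of symbol tuples, one per chain."""
    chains = []
    for i, symbols in enumerate(spec):
        cluster = gg.IfnCluster(
            f"sp{i}", "chr1", (_gene("I", 1000, True, species=f"sp{i}"),)
        )
        chains.append(gg.GeneChain(f"c{i}", f"sp{i}", cluster, tuple(symbols), tuple([0] * len(symbols))))
    return chains


class TestExtractConservedLoci:
    def test_threshold_gate_yields_empty_output(self):
        chains = _synthetic_chains([("A", f"u{i}") for i in range(15)])
        graph = gg.build_graph(chains)  # A has degree 15, not > 15
        assert gg.extract_conserved_loci(graph, min_degree=15) == []

    def test_hub_on_twenty_chains_extracted_then_loop_terminates(self):
        chains = _synthetic_chains(
            [("HUB", f"u{i}", f"v{i}") for i in range(20)]
            + [(f"w{i}", f"x{i}") for i in range(4)]
        )
        calls = gg.extract_conserved_loci(gg.build_graph(chains), min_degree=15)
        assert [(c.locus_symbol, c.degree_at_extraction, c.extraction_rank) for c in calls] == [
            ("HUB", 20, 1)
        ]

    def test_extraction_order_non_increasing_on_disjoint_chain_sets(self):
        spec = (
            [("A", f"a{i}") for i in range(25)]
            + [("B", f"b{i}") for i in range(20)]
            + [("C", f"c{i}") for i in range(18)]
        )
        calls = gg.extract_conserved_loci(gg.build_graph(_synthetic_chains(spec)), 15)
        assert [c.locus_symbol for c in calls] == ["A", "B", "C"]
        degrees = [c.degree_at_extraction for c in calls]
        assert degrees == sorted(degrees, reverse=True) == [25, 20, 18]

    def test_max_degree_tie_breaks_lexicographically(self):
        spec = [("ZZZ", "AAA", f"u{i}") for i in range(17)]
        calls = gg.extract_conserved_loci(gg.build_graph(_synthetic_chains(spec)), 15)
        # AAA and ZZZ tie at 17; AAA wins, and its removal deletes every chain
        assert [c.locus_symbol for c in calls] == ["AAA"]

    def test_species_degree_mode_collapses_same_species_chains(self):
        # one species contributes all 20 chains flanking HUB
        chains = []
        for i in range(20):
            cluster = gg.IfnCluster(
                "only_sp", "chr1", (_gene("I", 1000 + i, True, species="only_sp"),)
            )
            chains.append(
                gg.GeneChain(f"c{i}", "only_sp", cluster, ("HUB", f"u{i}"), (0, 0))
            )
        graph = gg.build_graph(chains)
        by_chains = gg.extract_conserved_loci(graph, min_degree=15, degree_mode="chains")
        by_species = gg.extract_conserved_loci(graph, min_degree=15, degree_mode="species")
        assert [c.locus_symbol for c in by_chains] == ["HUB"]
        assert by_species == []  # one species is not conservation

    def test_planted_anchors_recovered_from_pangenome(self, fast_pangenome):
        loci, _, _, _ = gg.run_locus_analysis(fast_pangenome.records_with_unannotated())
        assert sorted(c.locus_symbol for c in loci) == ["HACD4", "MOB3B", "UBAP2"]


class TestAssignLoci:
    def test_single_anchor_in_neighborhood(self):
        records = _layout("N I N")
        records[0] = _gene("HACD4", 1000)
        loci = [gg.LocusCall("HACD4", 20, 1)]
        (assignment,) = gg.assign_loci(
            [r for r in records if r.is_ifn1], loci, records
        )
        assert assignment.locus == "HACD4"
        assert assignment.distance == 1000

    def test_nearer_of_two_anchors_wins(self):
        ifn = _gene("IFN", 5000, is_ifn1=True)
        near = _gene("MOB3B", 5600)
        far = _gene("UBAP2", 6900)
        loci = [gg.LocusCall("UBAP2", 20, 1), gg.LocusCall("MOB3B", 18, 2)]
        (assignment,) = gg.assign_loci([ifn], loci, [ifn, near, far])
        assert assignment.locus == "MOB3B"

    def test_novel_flanks_fall_into_exception(self):
        records = _layout("N N I N N")
        loci = [gg.LocusCall("HACD4", 20, 1)]
        (assignment,) = gg.assign_loci([r for r in records if r.is_ifn1], loci, records)
        assert assignment.locus == gg.EXCEPTION and assignment.distance is None

    def test_assignment_is_total_and_dup_is_exception(self, fast_pangenome):
        records = fast_pangenome.records_with_unannotated()
        loci, assignments, _, _ = gg.run_locus_analysis(
            records, annotated_lookup=fast_pangenome.annotated_lookup()
        )
        ifn_genes = [r for r in records if r.is_ifn1]
        assert len(assignments) == len(ifn_genes)
        dup_chrom = fast_pangenome.truth.query("planted_locus == 'interchrom'")
        assert len(dup_chrom) == 1
        exceptions = [a for a in assignments if a.locus == gg.EXCEPTION]
        assert [a.ifn_gene.chromosome for a in exceptions] == ["chr2"]


class TestLocusSummary:
    def test_published_style_bookkeeping(self):
        """445+35, 71+15, 19+19 at three loci plus 21+6 exceptions = 95.7% of 631."""
        assignments = []

        def add(locus, annotated, unannotated):
            for i in range(annotated):
                assignments.append(
                    gg.LocusAssignment(_gene(f"I{len(assignments)}", 1000, True), locus, 0, True)
                )
            for i in range(unannotated):
                assignments.append(
                    gg.LocusAssignment(_gene(f"I{len(assignments)}", 1000, True), locus, 0, False)
                )

        add("HACD4", 445, 35)
        add("UBAP2", 71, 15)
        add("MOB3B", 19, 19)
        add(gg.EXCEPTION, 21, 6)
        summary, percent = gg.locus_summary(assignments)
        assert percent == 95.7
        assert int(summary["total"].sum()) == 631
        table = summary.set_index("locus")
        assert table.loc["HACD4", "annotated"] == 445
        assert table.loc["MOB3B", "unannotated"] == 19

    def test_boundary_percentages(self):
        a = [gg.LocusAssignment(_gene("I", 1000, True), "HACD4", 0)] * 4
        assert gg.locus_summary(a)[1] == 100.0
        b = [gg.LocusAssignment(_gene("I", 1000, True), gg.EXCEPTION, None)] * 4
        assert gg.locus_summary(b)[1] == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(EmptySummaryError):
            gg.locus_summary([])
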