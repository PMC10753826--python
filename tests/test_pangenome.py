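"""minbit filtering, Markov clustering, cluster bins and module completeness."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morelbiome.pangenome import (
    AnnotationTable,
    BitscoreTable,
    GeneClusterSet,
    KeggModule,
    build_similarity_graph,
    count_annotation_categories,
    estimate_metabolism,
    mcl_cluster,
    minbit,
    module_completeness,
    partition_clusters,
    presence_absence,
    read_annotations,
    read_bitscores,
    read_genome_map,
    read_modules,
    write_modules,
)
from morelbiome.pangenome import GenomeMap
from morelbiome.simulate import planted_clusters


class TestMinbit:
    def test_textbook_example(self):
        assert minbit(50, 100, 80) == pytest.approx(0.625)

    def test_equal_scores_give_one(self):
        assert minbit(42.0, 42.0, 42.0) == 1.0

    def test_zero_self_score_rejected(self):
        with pytest.raises(ValueError, match="self-score"):
            minbit(10, 0, 5)

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            ab, aa, bb = rng.uniform(1, 500, 3)
            assert minbit(ab, aa, bb) == pytest.approx(ab / min(aa, bb))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        ab=st.floats(0, 400),
        aa=st.floats(1, 500),
        bb=st.floats(1, 500),
    )
    def test_symmetric_in_self_scores(self, ab, aa, bb):
        assert minbit(ab, aa, bb) == minbit(ab, bb, aa)


def bitscores_from(pairs):
    """Helper: fill in self-scores as the max score involving each gene."""
    scores = dict(pairs)
    genes = {g for pair in scores for g in pair}
    for g in genes:
        best = max(
            (s for (a, b), s in scores.items() if g in (a, b)), default=100.0
        )
        scores.setdefault((g, g), best)
    return BitscoreTable(scores)


class TestSimilarityGraph:
    def test_minbit_below_threshold_drops_edge(self):
        bits = BitscoreTable({("a", "a"): 100, ("b", "b"): 100, ("a", "b"): 49})
        graph = build_similarity_graph(bits)
        assert not graph.has_edge("a", "b")
        assert graph.has_edge("a", "b") is False and len(graph) == 2

    def test_threshold_zero_keeps_all_scored_pairs(self):
        bits = BitscoreTable(
            {("a", "a"): 100, ("b", "b"): 100, ("c", "c"): 100,
             ("a", "b"): 1, ("b", "c"): 1}
        )
        graph = build_similarity_graph(bits, threshold=0.0)
        assert graph.number_of_edges() == 2

    def test_reciprocal_pairs_use_larger_bitscore(self):
        bits = BitscoreTable(
            {("a", "a"): 100, ("b", "b"): 100, ("a", "b"): 30, ("b", "a"): 60}
        )
        graph = build_similarity_graph(bits, threshold=0.5)
        assert graph.edges[("a", "b")]["weight"] == pytest.approx(0.6)

    def test_missing_self_score_names_gene(self):
        with pytest.raises(ValueError, match="b"):
            BitscoreTable({("a", "a"): 100, ("a", "b"): 50})

    def test_planted_fixture_edges_exactly_within_clusters(self, small_pangenome):
        _, (bitscores, genome_map, _, _) = small_pangenome
        graph = build_similarity_graph(bitscores)
        cluster_of = {g: g.split("|", 1)[1] for g in genome_map.genes}
        for a, b in graph.edges:
            assert cluster_of[a] == cluster_of[b]
        truth = planted_clusters(genome_map)
        for members in truth.values():
            sub = graph.subgraph(members)
            assert nx.is_connected(sub) if len(members) > 1 else True


class TestMcl:
    def test_two_disjoint_triangles(self):
        graph = nx.Graph()
        for offset in (0, 3):
            for i, j in itertools.combinations(range(offset, offset + 3), 2):
                graph.add_edge(f"n{i}", f"n{j}", weight=1.0)
        clusters = mcl_cluster(graph)
        assert len(clusters) == 2
        assert sorted(sorted(c) for c in clusters.clusters.values()) == [
            ["n0", "n1", "n2"],
            ["n3", "n4", "n5"],
        ]

    def test_single_node_is_singleton_cluster(self):
        graph = nx.Graph()
        graph.add_node("lonely")
        clusters = mcl_cluster(graph)
        assert len(clusters) == 1
        assert clusters.clusters["GC00001"] == frozenset({"lonely"})

    def test_output_is_partition_of_nodes(self, small_pangenome):
        _, (bitscores, genome_map, _, _) = small_pangenome
        graph = build_similarity_graph(bitscores)
        clusters = mcl_cluster(graph)
        all_members = [g for ms in clusters.clusters.values() for g in ms]
        assert sorted(all_members) == sorted(graph.nodes)

    def test_planted_partition_recovered_exactly(self, small_pangenome):
        from sklearn.metrics import adjusted_rand_score

        _, (bitscores, genome_map, _, _) = small_pangenome
        clusters = mcl_cluster(build_similarity_graph(bitscores))
        truth = planted_clusters(genome_map)
        truth_label = {g: cid for cid, ms in truth.items() for g in ms}
        ours = clusters.labels()
        genes = sorted(ours)
        ari = adjusted_rand_score(
            [truth_label[g] for g in genes], [ours[g] for g in genes]
        )
        assert ari == 1.0

    def test_clusters_never_span_components(self):
        rng = np.random.default_rng(15)
        graph = nx.Graph()
        # three random connected blobs with no cross edges
        for b in range(3):
            nodes = [f"b{b}n{i}" for i in range(6)]
            for i, j in itertools.combinations(range(6), 2):
                if rng.random() < 0.6:
                    graph.add_edge(nodes[i], nodes[j], weight=rng.uniform(0.5, 1.0))
            comp = graph.subgraph(nodes)
            for i in range(5):  # ensure connectivity inside the blob
                graph.add_edge(nodes[i], nodes[i + 1], weight=1.0)
        clusters = mcl_cluster(graph)
        comp_of = {}
        for k, comp in enumerate(nx.connected_components(graph)):
            for n in comp:
                comp_of[n] = k
        for members in clusters.clusters.values():
            assert len({comp_of[m] for m in members}) == 1

    def test_higher_inflation_never_coarsens(self):
        # two weakly-bridged cliques: low inflation may merge them, high
        # inflation must split at least as finely
        graph = nx.Graph()
        for offset in (0, 4):
            for i, j in itertools.combinations(range(offset, offset + 4), 2):
                graph.add_edge(f"n{i}", f"n{j}", weight=1.0)
        graph.add_edge("n3", "n4", weight=0.6)
        coarse = mcl_cluster(graph, inflation=1.3)
        fine = mcl_cluster(graph, inflation=4.0)
        assert len(fine) >= len(coarse)
        coarse_of = fine_to_coarse = {
            g: cid for cid, ms in coarse.clusters.items() for g in ms
        }
        for members in fine.clusters.values():
            assert len({coarse_of[m] for m in members}) == 1  # refinement

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mcl_cluster(nx.Graph())


class TestPartition:
    def test_bins_on_planted_fixture(self, small_pangenome):
        _, (bitscores, genome_map, _, _) = small_pangenome
        clusters = mcl_cluster(build_similarity_graph(bitscores))
        bins = partition_clusters(clusters, genome_map)
        assert len(bins.core) == 5
        assert bins.n_unique_total == 6
        assert all(len(u) == 2 for u in bins.unique.values())
        assert not bins.accessory

    def test_bins_cover_cluster_set_disjointly(self):
        from morelbiome.simulate import PangenomeSimConfig, generate_pangenome

        cfg = PangenomeSimConfig(seed=6)
        bitscores, genome_map, _, _ = generate_pangenome(cfg)
        clusters = mcl_cluster(build_similarity_graph(bitscores))
        bins = partition_clusters(clusters, genome_map, group=("G1", "G2", "G3"))
        pieces = [bins.core, bins.group_core, bins.accessory, *bins.unique.values()]
        union = set().union(*pieces)
        assert union == set(clusters.clusters)
        assert sum(len(p) for p in pieces) == len(union)
        assert len(bins.group_core) == 12

    def test_unknown_group_genome_rejected(self, small_pangenome):
        _, (bitscores, genome_map, _, _) = small_pangenome
        clusters = GeneClusterSet(planted_clusters(genome_map))
        with pytest.raises(ValueError, match="unknown"):
            partition_clusters(clusters, genome_map, group=("G1", "nope"))


class TestModuleCompleteness:
    def test_three_of_four_steps_is_complete(self):
        module = KeggModule("M1", [frozenset({f"K{i}"}) for i in range(4)])
        res = module_completeness(module, {"K0", "K1", "K2"})
        assert res.completeness == pytest.approx(0.75)
        assert res.complete

    def test_no_kos_incomplete(self):
        module = KeggModule("M1", [frozenset({"K1"}), frozenset({"K2"})])
        res = module_completeness(module, set())
        assert res.completeness == 0.0
        assert not res.complete

    def test_any_alternative_satisfies_step(self):
        module = KeggModule("M1", [frozenset({"K1", "K2"})])
        assert module_completeness(module, {"K2"}).complete

    def test_empty_module_rejected(self):
        with pytest.raises(ValueError, match="steps"):
            KeggModule("M1", [])
        with pytest.raises(ValueError, match="empty step"):
            KeggModule("M1", [frozenset()])

    def test_exhaustive_agreement_with_direct_counting(self):
        """All KO subsets of small modules: completeness equals the literal
        satisfied-step count, including the 0.75 boundary."""
        rng = np.random.default_rng(2)
        for n_steps in range(1, 7):
            kos = [f"K{i}" for i in range(n_steps + 2)]
            steps = [
                frozenset(rng.choice(kos, size=rng.integers(1, 3), replace=False))
                for _ in range(n_steps)
            ]
            module = KeggModule("M", steps)
            for r in range(len(kos) + 1):
                for subset in itertools.combinations(kos, r):
                    present = set(subset)
                    expected = sum(1 for s in steps if s & present) / n_steps
                    res = module_completeness(module, present)
                    assert res.completeness == pytest.approx(expected)
                    assert res.complete == (expected >= 0.75)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_monotone_in_ko_set(self, data):
        kos = [f"K{i}" for i in range(8)]
        steps = data.draw(
            st.lists(
                st.sets(st.sampled_from(kos), min_size=1, max_size=3),
                min_size=1,
                max_size=6,
            )
        )
        module = KeggModule("M", [frozenset(s) for s in steps])
        small = set(data.draw(st.sets(st.sampled_from(kos), max_size=5)))
        extra = set(data.draw(st.sets(st.sampled_from(kos), max_size=5)))
        c_small = module_completeness(module, small).completeness
        c_big = module_completeness(module, small | extra).completeness
        assert c_big >= c_small


class TestAnnotationsAndIo:
    def test_empty_annotations_zero_counts(self):
        ann = AnnotationTable(pd.DataFrame(columns=["gene_id", "ko", "category"]))
        gmap = GenomeMap({"g1": "G1"})
        counts = count_annotation_categories(ann, gmap)
        assert counts["total"].tolist() == [0]

    def test_family_counted_per_genome(self):
        ann = AnnotationTable(
            pd.DataFrame(
                {
                    "gene_id": ["g1", "g2", "g3", "g4"],
                    "ko": [""] * 4,
                    "category": ["GH1", "GH1", "GH1", "GT2"],
                }
            )
        )
        gmap = GenomeMap({"g1": "G1", "g2": "G1", "g3": "G1", "g4": "G2"})
        counts = count_annotation_categories(ann, gmap)
        assert counts.at["G1", "GH1"] == 3
        assert counts.at["G2", "GT2"] == 1
        assert counts.at["G1", "total"] == 3

    def test_planted_category_counts_recovered(self, small_pangenome):
        cfg, (_, genome_map, annotations, _) = small_pangenome
        counts = count_annotation_categories(annotations, genome_map)
        # one annotated gene per category per genome (categories ride on the
        # first n_categories core clusters)
        expected = min(cfg.n_categories, cfg.n_core_clusters)
        assert (counts["total"] == expected).all()

    def test_bitscore_and_map_roundtrip(self, tmp_path, small_pangenome):
        _, (bitscores, genome_map, annotations, modules) = small_pangenome
        bitscores.to_tsv(tmp_path / "b.tsv")
        genome_map.to_tsv(tmp_path / "g.tsv")
        annotations.to_tsv(tmp_path / "a.tsv")
        back = read_bitscores(tmp_path / "b.tsv")
        assert back.scores == pytest.approx(bitscores.scores)
        assert read_genome_map(tmp_path / "g.tsv").mapping == genome_map.mapping
        assert read_annotations(tmp_path / "a.tsv").table.equals(annotations.table)

    def test_module_file_roundtrip(self, tmp_path):
        modules = [
            KeggModule("M1", [frozenset({"K1", "K2"}), frozenset({"K3"})]),
            KeggModule("M2", [frozenset({"K9"})]),
        ]
        write_modules(modules, tmp_path / "m.tsv")
        back = read_modules(tmp_path / "m.tsv")
        assert [(m.module_id, m.steps) for m in back] == [
            (m.module_id, m.steps) for m in modules
        ]
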