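import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bpfs import (
    NO_PATH,
    UNRESOLVED,
    GeneMapping,
    InfluenceModel,
    PathwayGraph,
    average_reachability,
    consolidate,
    estimate_p,
    fit_reachability_curve,
    fully_connected_graph,
    hop_distance,
    influence_factor,
    subsample_edges,
    total_influence,
)
from conftest import bfs_oracle, random_graph


class TestConsolidate:
    def test_union_deduplicates_shared_edges(self, tmp_path):
        f1, f2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        f1.write_text("g1\tg2\ng2\tg3\n")
        f2.write_text("g1\tg2\ng3\tg4\n")
        g = consolidate([f1, f2])
        assert g.n_edges == 3

    def test_self_loop_dropped_vertex_kept(self):
        g = consolidate([[("a", "a"), ("a", "b")]])
        assert "a" in g and g.n_edges == 1

    def test_sif_middle_column_ignored(self, tmp_path):
        f = tmp_path / "a.sif"
        f.write_text("g1\tactivates\tg2\ng2\tinhibits\tg3\n")
        assert consolidate([f]).n_edges == 2

    def test_fig1_edges(self, fig1):
        graph, _ = fig1
        assert graph.n_edges == 7
        assert graph.vertices == {
            "PKB/Akt", "CASP9", "IKK", "NFkB", "BAD", "Bcl-xl", "RacGEF", "RAC",
        }

    def test_empty_union_rejected(self):
        with pytest.raises(ValueError):
            consolidate([[]])


class TestHopDistance:
    @pytest.mark.parametrize(
        "a,b,d",
        [("PKB/Akt", "CASP9", 1), ("PKB/Akt", "NFkB", 2), ("RacGEF", "NFkB", 2)],
    )
    def test_worked_example_distances(self, fig1, a, b, d):
        graph, _ = fig1
        assert hop_distance(graph, a, b) == d
        assert hop_distance(graph, b, a) == d  # symmetric

    def test_disconnected_is_no_path(self):
        g = consolidate([[("a", "b"), ("c", "d")]])
        assert hop_distance(g, "a", "c") is NO_PATH

    def test_unknown_vertex_rejected(self, fig1):
        graph, _ = fig1
        with pytest.raises(KeyError):
            hop_distance(graph, "PKB/Akt", "nope")

    def test_matches_bfs_oracle_on_random_graphs(self):
        for seed in range(20):
            g = random_graph(30, 0.08, seed)
            src = seed % 30
            oracle = bfs_oracle(g, src)
            for v in g.graph.nodes:
                expected = oracle.get(v, NO_PATH)
                assert hop_distance(g, src, v) == expected


class TestInfluenceFactor:
    def test_one_hop_is_one(self, fig1):
        graph, _ = fig1
        assert influence_factor(InfluenceModel(), graph, "PKB/Akt", "CASP9") == 1.0

    def test_two_hops_is_half(self, fig1):
        graph, _ = fig1
        assert influence_factor(InfluenceModel(), graph, "PKB/Akt", "NFkB") == 0.5

    def test_disconnected_default_zero(self):
        g = consolidate([[("a", "b"), ("c", "d")]])
        assert influence_factor(InfluenceModel(), g, "a", "c") == 0.0

    def test_identical_genes_rejected(self, fig1):
        graph, _ = fig1
        with pytest.raises(ValueError):
            influence_factor(InfluenceModel(), graph, "IKK", "IKK")

    def test_halves_per_extra_hop(self):
        # path graph: distance k from one end
        g = consolidate([[(f"n{i}", f"n{i+1}") for i in range(6)]])
        model = InfluenceModel()
        prev = influence_factor(model, g, "n0", "n1")
        for k in range(2, 7):
            cur = influence_factor(model, g, "n0", f"n{k}")
            assert cur == pytest.approx(prev / 2)
            prev = cur


class TestTotalInfluence:
    def test_worked_example(self, fig1):
        graph, mapping = fig1
        tif = total_influence(InfluenceModel(), graph, mapping, "PKB/Akt", ["CASP9", "NFkB"])
        assert tif == 1.5

    def test_unresolved_candidate_is_p_times_s(self, fig1):
        graph, _ = fig1
        mapping = GeneMapping({"x": UNRESOLVED, **{g: g for g in graph.vertices}})
        model = InfluenceModel(p=0.0088)
        sel = ["CASP9", "NFkB", "IKK"]
        assert total_influence(model, graph, mapping, "x", sel) == pytest.approx(0.0088 * 3)

    def test_mixed_selected_set(self, fig1):
        graph, _ = fig1
        mapping = GeneMapping({"u1": UNRESOLVED, "u2": UNRESOLVED, **{g: g for g in graph.vertices}})
        model = InfluenceModel(p=0.01)
        tif = total_influence(model, graph, mapping, "PKB/Akt", ["CASP9", "u1", "u2"])
        assert tif == pytest.approx(1.0 + 2 * 0.01)

    def test_empty_selected_is_zero(self, fig1):
        graph, mapping = fig1
        assert total_influence(InfluenceModel(), graph, mapping, "PKB/Akt", []) == 0.0

    def test_candidate_in_selected_rejected(self, fig1):
        graph, mapping = fig1
        with pytest.raises(ValueError):
            total_influence(InfluenceModel(), graph, mapping, "IKK", ["IKK"])

    def test_nondecreasing_as_selected_grows(self, fig1):
        graph, mapping = fig1
        model = InfluenceModel(p=0.0088)
        sel = []
        prev = 0.0
        for s in ["CASP9", "NFkB", "BAD", "RAC"]:
            sel.append(s)
            cur = total_influence(model, graph, mapping, "PKB/Akt", sel)
            assert cur >= prev
            prev = cur

    @given(st.integers(min_value=0, max_value=100), st.floats(min_value=0, max_value=1))
    @settings(max_examples=30, deadline=None)
    def test_all_unresolved_equals_p_times_size(self, size, p):
        mapping = GeneMapping({f"f{i}": UNRESOLVED for i in range(size + 1)})
        graph = PathwayGraph(nx.Graph([("a", "b")]))
        model = InfluenceModel(p=p)
        sel = [f"f{i}" for i in range(size)]
        assert total_influence(model, graph, mapping, f"f{size}", sel) == pytest.approx(p * size)


class TestFullyConnectedGraph:
    def test_clique_edge_counts(self):
        member = {f"a{i}": "P1" for i in range(3)} | {f"b{i}": "P2" for i in range(2)}
        g = fully_connected_graph(member)
        assert g.n_edges == 4  # C(3,2) + C(2,2)

    def test_intra_pathway_influence_one_cross_zero(self):
        member = {"a": "P1", "b": "P1", "c": "P2", "d": "P2"}
        g = fully_connected_graph(member)
        model = InfluenceModel()
        assert influence_factor(model, g, "a", "b") == 1.0
        assert influence_factor(model, g, "a", "c") == 0.0

    def test_unmapped_genes_are_singletons(self):
        g = fully_connected_graph({"a": "P1", "b": "P1"}, all_genes=["lonely"])
        assert "lonely" in g
        assert g.graph.degree["lonely"] == 0

    def test_multi_pathway_gene_joins_all_cliques(self):
        member = {"a": {"P1", "P2"}, "b": "P1", "c": "P2"}
        g = fully_connected_graph(member)
        assert hop_distance(g, "b", "a") == 1 and hop_distance(g, "c", "a") == 1
        assert hop_distance(g, "b", "c") == 2  # no direct cross-pathway edge


class TestSubsampleEdges:
    def test_fraction_one_identical(self, fig1):
        graph, _ = fig1
        sub = subsample_edges(graph, 1.0, seed=0)
        assert set(map(frozenset, sub.graph.edges)) == set(map(frozenset, graph.graph.edges))

    @pytest.mark.parametrize("fraction", [0.1, 0.25, 0.5, 0.73, 0.9])
    def test_retains_rounded_count(self, fraction):
        g = random_graph(40, 0.15, seed=1)
        n_edges = g.n_edges
        sub = subsample_edges(g, fraction, seed=2)
        assert sub.n_edges == int(round(fraction * n_edges))
        assert sub.vertices == g.vertices

    def test_deterministic_under_seed(self):
        g = random_graph(30, 0.2, seed=0)
        a = subsample_edges(g, 0.5, seed=9)
        b = subsample_edges(g, 0.5, seed=9)
        assert set(a.graph.edges) == set(b.graph.edges)


class TestAverageReachability:
    def test_complete_graph(self):
        g = PathwayGraph(nx.complete_graph(5))
        assert average_reachability(g) == 4.0

    def test_edgeless_graph(self):
        g = PathwayGraph(nx.empty_graph(6))
        assert average_reachability(g) == 0.0

    def test_matches_bfs_oracle(self):
        for seed in range(20):
            g = random_graph(25, 0.07, seed)
            expected = np.mean([len(bfs_oracle(g, v)) - 1 for v in g.graph.nodes])
            assert average_reachability(g) == pytest.approx(expected)


class TestReachabilityCurveFit:
    def test_noiseless_recovery(self):
        s = np.arange(10, 101, 10, dtype=float)
        r = 180 - 170 * 0.97**s
        curve = fit_reachability_curve(s, r)
        assert curve.asymptote == pytest.approx(180, rel=1e-6)
        assert curve.amplitude == pytest.approx(170, rel=1e-6)
        assert curve.ratio == pytest.approx(0.97, rel=1e-6)

    def test_constant_data_saturated(self):
        s = np.arange(10, 101, 10, dtype=float)
        curve = fit_reachability_curve(s, np.full(10, 42.0))
        assert curve.asymptote == pytest.approx(42.0)
        assert curve.amplitude == pytest.approx(0.0, abs=1e-9)

    def test_noisy_recovery_within_five_percent(self):
        rng = np.random.default_rng(0)
        s = np.arange(10, 101, 10, dtype=float)
        errs = []
        for _ in range(50):
            r = 180 - 170 * 0.97**s + rng.normal(0, 1, size=10)
            curve = fit_reachability_curve(s, r)
            errs.append(abs(curve.asymptote - 180) / 180)
        assert np.mean(errs) < 0.05

    def test_fitted_curve_nondecreasing(self):
        s = np.arange(10, 101, 10, dtype=float)
        r = 150 - 140 * 0.96**s
        curve = fit_reachability_curve(s, r)
        grid = curve(np.linspace(10, 600, 200))
        assert np.all(np.diff(grid) >= -1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_reachability_curve([10, 20, 30], [1, 2, 3])


class TestEstimateP:
    def make_curve(self, A):
        s = np.arange(10, 101, 10, dtype=float)
        return fit_reachability_curve(s, A - (A - 10) * 0.97**s)

    def test_reported_value_rounds_to_00088(self):
        curve = self.make_curve(180.0)
        p = estimate_p(curve, total_genes=20500)
        assert round(p, 4) == 0.0088

    def test_zero_reachability_gives_zero(self):
        s = np.arange(10, 101, 10, dtype=float)
        curve = fit_reachability_curve(s, np.zeros(10))
        assert estimate_p(curve, total_genes=20500) == 0.0

    def test_clamped_to_one(self):
        curve = self.make_curve(30000.0)
        assert estimate_p(curve, total_genes=20500) == 1.0

    def test_extrapolate_to_specific_s(self):
        curve = self.make_curve(180.0)
        p500 = estimate_p(curve, total_genes=20500, extrapolate_to=500)
        assert p500 == pytest.approx(curve(500) / 20500)
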