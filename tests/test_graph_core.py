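"""Core graph container and the four evaluation measures."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netpattern import graph_core as gc
from netpattern.generators import er_gnm, er_gnp

from conftest import brute_clustering, brute_triangles, complete_graph, dense_pagerank


def small_graph_strategy():
    """Random simple graphs with <= 12 nodes as (n, edge list) pairs."""

    @st.composite
    def build(draw):
        n = draw(st.integers(min_value=1, max_value=12))
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        chosen = draw(st.lists(st.sampled_from(pairs), max_size=len(pairs))) if pairs else []
        return gc.Graph.from_edges(chosen, nodes=range(n))

    return build()


# ----------------------------------------------------------------- container


class TestGraph:
    def test_symmetrize_dedupe_and_drop_self_loops(self):
        g = gc.Graph.from_edges([("a", "b"), ("b", "a"), ("a", "a"), ("b", "c")])
        assert g.n_nodes == 3
        assert g.edge_set() == {frozenset({"a", "b"}), frozenset({"b", "c"})}

    def test_isolated_nodes_retained(self):
        g = gc.Graph.from_edges([(1, 2)], nodes=[1, 2, 3, 4])
        assert g.n_nodes == 4
        assert g.degrees()[3] == 0

    def test_edge_endpoints_must_be_nodes(self):
        with pytest.raises(gc.GraphError):
            gc.Graph(range(2), np.array([[0, 5]]))

    def test_edgelist_roundtrip(self, tmp_path):
        g = gc.Graph.from_edges([("n1", "n2"), ("n2", "n3")])
        path = tmp_path / "edges.tsv"
        gc.write_edgelist(g, path, header=True)
        back = gc.read_edgelist(path, skip_header=True)
        assert back.edge_set() == g.edge_set()

    def test_report_is_json_serializable(self, k4, tmp_path):
        gc.write_report(k4, tmp_path / "rep.json")
        rep = json.loads((tmp_path / "rep.json").read_text())
        assert rep["n_nodes"] == 4 and rep["avg_degree"] == 3.0


# ------------------------------------------------------------------ measures


class TestAverageDegree:
    def test_printed_worm_counts(self):
        g = er_gnm(281, 2405, seed=1)
        assert gc.average_degree(g) == pytest.approx(17.1174, abs=1e-4)

    def test_no_edges_and_k4(self, k4):
        assert gc.average_degree(gc.Graph.from_edges([], nodes=range(5))) == 0.0
        assert gc.average_degree(k4) == 3.0

    def test_empty_graph_raises(self):
        with pytest.raises(gc.EmptyGraphError):
            gc.average_degree(gc.Graph.from_edges([]))


class TestPageRank:
    def test_single_isolated_node(self):
        assert gc.pagerank_vector(gc.Graph.from_edges([], nodes=["v"])) == {"v": 1.0}

    def test_cycle_is_uniform(self):
        n = 7
        g = gc.Graph.from_edges([(i, (i + 1) % n) for i in range(n)])
        pr = gc.pagerank_vector(g)
        assert all(abs(v - 1 / n) < 1e-9 for v in pr.values())

    def test_toy_graph_matches_dense_oracle(self):
        g = gc.Graph.from_edges([(0, 1), (1, 2), (2, 3), (1, 3)])
        pr = gc.pagerank_vector(g)
        oracle = dense_pagerank(g)
        for v in g.node_list:
            assert pr[v] == pytest.approx(oracle[v], abs=1e-8)

    def test_average_equals_reciprocal_node_count(self):
        g = er_gnp(281, 0.0611, seed=3)
        assert gc.average_pagerank(g) == pytest.approx(1 / 281, abs=1e-9)
        assert round(gc.average_pagerank(g), 4) == 0.0036

    def test_nonconvergence_warns(self):
        # a star is far from its stationary distribution after one sweep
        g = gc.Graph.from_edges([("h", i) for i in range(5)])
        with pytest.warns(gc.PageRankConvergenceWarning):
            gc.pagerank_vector(g, max_iter=1, tol=1e-15)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(small_graph_strategy())
    def test_mass_sums_to_one(self, g):
        assert sum(gc.pagerank_vector(g).values()) == pytest.approx(1.0, abs=1e-9)


class TestTriangles:
    def test_cliques_and_path(self, k4):
        k3 = complete_graph(3)
        assert set(gc.node_triangle_counts(k3).values()) == {1}
        assert set(gc.node_triangle_counts(k4).values()) == {3}
        path = gc.Graph.from_edges([("a", "b"), ("b", "c")])
        assert set(gc.node_triangle_counts(path).values()) == {0}

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(small_graph_strategy())
    def test_matches_exhaustive_enumeration(self, g):
        assert gc.node_triangle_counts(g) == brute_triangles(g)

    def test_average_triangles_k4(self, k4):
        assert gc.average_triangles(k4) == 3.0


class TestClustering:
    def test_known_cases(self, k4):
        k3 = complete_graph(3)
        assert gc.node_clustering(k3, 0) == 1.0
        star = gc.Graph.from_edges([("h", i) for i in range(5)])
        assert gc.node_clustering(star, "h") == 0.0  # hub
        assert gc.node_clustering(star, 0) == 0.0  # degree-1 convention
        assert gc.average_clustering(k3) == 1.0
        assert gc.average_clustering(gc.Graph.from_edges([], nodes=range(4))) == 0.0

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(small_graph_strategy())
    def test_matches_brute_force_and_bounds(self, g):
        oracle = brute_clustering(g)
        arr = gc._clustering_array(g)
        for i, v in enumerate(g.node_list):
            assert arr[i] == pytest.approx(oracle[v], abs=1e-12)
        assert 0.0 <= gc.average_clustering(g) <= 1.0
        assert gc.average_degree(g) <= max(g.n_nodes - 1, 0)


class TestEdgeProbability:
    def test_printed_densities(self):
        worm = er_gnm(281, 2405, seed=1)
        assert gc.edge_probability(worm) == pytest.approx(0.061134, abs=1e-6)
        assert gc.edge_probability(complete_graph(6)) == 1.0

    def test_requires_two_nodes(self):
        with pytest.raises(gc.GraphError):
            gc.edge_probability(gc.Graph.from_edges([], nodes=["v"]))


class TestMeasureVector:
    def test_k4_bundle(self, k4):
        mv = gc.measure_vector(k4)
        assert (mv.avg_degree, mv.avg_pagerank, mv.avg_clustering, mv.avg_triangles) == (
            3.0, pytest.approx(0.25, abs=1e-9), 1.0, 3.0,
        )

    def test_edgeless_bundle(self):
        mv = gc.measure_vector(gc.Graph.from_edges([], nodes=range(8)))
        assert mv.avg_degree == 0.0
        assert mv.avg_pagerank == pytest.approx(1 / 8, abs=1e-9)
        assert mv.avg_clustering == 0.0 and mv.avg_triangles == 0.0

    def test_mean_requires_vectors(self):
        with pytest.raises(ValueError):
            gc.MeasureVector.mean([])


class TestErdosRenyiExpectations:
    """Measure means on G(n,p) draws agree with the closed forms."""

    @pytest.mark.parametrize("n", [100, 281])
    def test_clustering_tracks_p(self, n):
        p = 0.0611
        vals = [gc.average_clustering(er_gnp(n, p, s)) for s in range(25)]
        se = np.std(vals, ddof=1) / math.sqrt(len(vals))
        assert abs(np.mean(vals) - p) < 3 * se + 1e-4

    def test_triangles_match_closed_form(self):
        n, p = 281, 0.0611
        expected = math.comb(n - 1, 2) * p**3
        vals = [gc.average_triangles(er_gnp(n, p, s)) for s in range(25)]
        se = np.std(vals, ddof=1) / math.sqrt(len(vals))
        assert abs(np.mean(vals) - expected) < 3 * se + 0.02


class TestPearson:
    def test_degenerate_and_bounds(self):
        assert math.isnan(gc.pearson([1, 1, 1], [1, 2, 3]))
        assert gc.pearson([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            gc.pearson([1], [2])
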