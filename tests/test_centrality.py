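"""Centrality measures vs closed forms and brute-force path enumeration."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from pvatgrn import (
    GRNModel,
    betweenness_centrality,
    centrality_table,
    degree_out_centrality,
    eigenvector_centrality,
)
from pvatgrn.errors import InvalidParameterError


def model_from_edges(edges, genes=None):
    frame = pd.DataFrame(edges, columns=["regulator", "target", "coefficient"])
    frame["sign_consistency"] = 1.0
    genes = genes or sorted(set(frame["regulator"]) | set(frame["target"]))
    return GRNModel(condition="test", edges=frame, genes=genes)


def brute_force_betweenness(g: nx.DiGraph) -> dict:
    """Independent oracle: enumerate all shortest paths between ordered pairs."""
    n = g.number_of_nodes()
    score = {v: 0.0 for v in g.nodes}
    for s, t in itertools.permutations(g.nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        sigma = len(paths)
        for path in paths:
            for v in path[1:-1]:
                score[v] += 1.0 / sigma
    if n > 2:
        for v in score:
            score[v] /= (n - 1) * (n - 2)
    return score


class TestEigenvector:
    def test_two_nodes_single_edge_symmetric(self):
        m = model_from_edges([("a", "b", 5.0)])
        scores = eigenvector_centrality(m)
        assert scores["a"] == pytest.approx(scores["b"])
        assert np.linalg.norm(scores.to_numpy()) == pytest.approx(1.0)

    def test_scale_invariance(self):
        edges = [("a", "b", 0.3), ("b", "c", -1.2), ("a", "c", 0.7)]
        s1 = eigenvector_centrality(model_from_edges(edges))
        s2 = eigenvector_centrality(
            model_from_edges([(u, v, 10 * w) for u, v, w in edges])
        )
        pd.testing.assert_series_equal(s1, s2, atol=1e-8)

    def test_star_graph_center_leaf_ratio_is_two(self):
        # closed form: undirected star with k leaves has center/leaf = sqrt(k)
        m = model_from_edges([("hub", f"leaf{i}", 1.0) for i in range(4)])
        scores = eigenvector_centrality(m)
        assert scores["hub"] / scores["leaf0"] == pytest.approx(2.0, rel=1e-6)

    def test_matches_dense_eigendecomposition(self):
        rng = np.random.default_rng(0)
        nodes = [f"n{i}" for i in range(8)]
        edges = [
            (nodes[i], nodes[j], rng.normal())
            for i in range(8)
            for j in range(8)
            if i != j and rng.random() < 0.35
        ]
        m = model_from_edges(edges, genes=nodes)
        scores = eigenvector_centrality(m, tol=1e-12)
        a = np.zeros((8, 8))
        idx = {v: k for k, v in enumerate(nodes)}
        for u, v, w in edges:
            a[idx[u], idx[v]] = abs(w)
        a = a + a.T
        vals, vecs = np.linalg.eigh(a)
        lead = np.abs(vecs[:, np.argmax(vals)])
        got = scores.reindex(nodes).to_numpy()
        np.testing.assert_allclose(got, lead / np.linalg.norm(lead), atol=1e-6)

    def test_eigen_equation_residual_within_tolerance(self):
        edges = [("a", "b", 1.0), ("b", "c", 2.0), ("c", "d", 0.5), ("a", "d", 1.5)]
        m = model_from_edges(edges)
        v = eigenvector_centrality(m, tol=1e-12)
        nodes = list(v.index)
        a = np.zeros((len(nodes), len(nodes)))
        idx = {n: i for i, n in enumerate(nodes)}
        for u, w_, c in edges:
            a[idx[u], idx[w_]] = abs(c)
        a = a + a.T
        vec = v.to_numpy()
        lam = vec @ a @ vec
        assert np.linalg.norm(a @ vec - lam * vec) < 1e-6

    def test_edgeless_graph_warns_all_zero(self):
        m = model_from_edges([], genes=["a", "b"])
        m.edges = pd.DataFrame(
            columns=["regulator", "target", "coefficient", "sign_consistency"]
        )
        with pytest.warns(UserWarning):
            scores = eigenvector_centrality(m)
        assert (scores == 0).all()


class TestDegreeOut:
    def test_full_out_star_is_one(self):
        m = model_from_edges([("hub", f"t{i}", 1.0) for i in range(5)])
        assert degree_out_centrality(m)["hub"] == 1.0

    def test_isolated_node_zero(self):
        m = model_from_edges([("a", "b", 1.0)], genes=["a", "b", "loner"])
        assert degree_out_centrality(m)["loner"] == 0.0

    def test_matches_neighbor_counting(self):
        rng = np.random.default_rng(1)
        nodes = [f"n{i}" for i in range(10)]
        edges = [
            (u, v, 1.0) for u in nodes for v in nodes if u != v and rng.random() < 0.3
        ]
        m = model_from_edges(edges, genes=nodes)
        scores = degree_out_centrality(m)
        for u in nodes:
            expected = len({v for (a, v, _) in edges if a == u}) / 9
            assert scores[u] == pytest.approx(expected)

    def test_isolated_node_shifts_denominator_only(self):
        edges = [("a", "b", 1.0), ("a", "c", 1.0)]
        d3 = degree_out_centrality(model_from_edges(edges))
        d4 = degree_out_centrality(model_from_edges(edges, genes=["a", "b", "c", "x"]))
        assert d3["a"] * 2 == pytest.approx(d4["a"] * 3)  # numerator unchanged


class TestBetweenness:
    def test_complete_digraph_all_zero(self):
        nodes = ["a", "b", "c", "d"]
        m = model_from_edges(
            [(u, v, 1.0) for u in nodes for v in nodes if u != v], genes=nodes
        )
        assert (betweenness_centrality(m) == 0).all()

    def test_directed_path_middle_node(self):
        m = model_from_edges([("a", "b", 1.0), ("b", "c", 1.0)])
        scores = betweenness_centrality(m)
        assert scores["b"] == pytest.approx(0.5)  # 1 path / ((3-1)(3-2))
        assert scores["a"] == 0 and scores["c"] == 0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 8))
        nodes = [f"n{i}" for i in range(n)]
        edges = [
            (u, v, rng.normal())
            for u in nodes
            for v in nodes
            if u != v and rng.random() < 0.35
        ]
        m = model_from_edges(edges, genes=nodes)
        got = betweenness_centrality(m)
        expected = brute_force_betweenness(m.to_graph())
        for v in nodes:
            assert got[v] == pytest.approx(expected[v], abs=1e-12)


def test_centrality_table_shape_and_bounds(fitted_pair):
    table = centrality_table(fitted_pair["control"])
    assert set(table.columns) == {"condition", "eigenvector", "degree_out", "betweenness"}
    vals = table[["eigenvector", "degree_out", "betweenness"]]
    assert np.isfinite(vals.to_numpy()).all()
    assert (vals >= 0).all().all()
    assert (table["degree_out"] <= 1).all() and (table["betweenness"] <= 1).all()


def test_empty_graph_rejected():
    m = GRNModel(
        condition="x",
        edges=pd.DataFrame(columns=["regulator", "target", "coefficient", "sign_consistency"]),
        genes=[],
    )
    with pytest.raises(InvalidParameterError):
        eigenvector_centrality(m)
    with pytest.raises(InvalidParameterError):
        degree_out_centrality(m)
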