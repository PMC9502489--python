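"""Sparsity thresholding, graph metrics, null models and AUC."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mbnet import (
    BinaryGraph,
    MetricCurve,
    auc_over_sparsity,
    global_metrics,
    nodal_metrics,
    random_reference,
    small_world_indices,
    sparsity_grid,
    sweep_metrics,
    threshold_by_sparsity,
)


def graph(edges, n):
    adj = np.zeros((n, n), dtype=bool)
    for i, j in edges:
        adj[i, j] = adj[j, i] = True
    return BinaryGraph(adjacency=adj)


def floyd_warshall(adj):
    """Independent O(n^3) all-pairs shortest paths."""
    n = adj.shape[0]
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    D[adj] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                D[i, j] = min(D[i, j], D[i, k] + D[k, j])
    return D


def brute_betweenness(adj):
    """Betweenness from the shortest-path counting identity (not Brandes)."""
    n = adj.shape[0]
    D = floyd_warshall(adj)
    sigma = np.zeros((n, n))
    for s in range(n):
        sigma[s, s] = 1.0
        for dist in range(1, n):
            for t in range(n):
                if D[s, t] == dist:
                    sigma[s, t] = sum(sigma[s, u] for u in np.flatnonzero(adj[:, t]) if D[s, u] == dist - 1)
    bc = np.zeros(n)
    for v in range(n):
        for s, t in itertools.combinations([u for u in range(n) if u != v], 2):
            if np.isfinite(D[s, t]) and sigma[s, t] > 0 and D[s, v] + D[v, t] == D[s, t]:
                bc[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    return bc / ((n - 1) * (n - 2) / 2)


def random_graph(n, p, seed):
    rng = np.random.default_rng(seed)
    adj = np.triu(rng.random((n, n)) < p, k=1)
    return BinaryGraph(adjacency=adj | adj.T)


class TestThreshold:
    def test_keeps_the_largest_weights(self):
        rng = np.random.default_rng(0)
        W = np.zeros((5, 5))
        iu = np.triu_indices(5, 1)
        W[iu] = rng.permutation(10) + 1.0
        W += W.T
        g = threshold_by_sparsity(W, 0.4)  # floor(0.4 * 10) = 4 edges
        assert g.n_edges == 4
        kept = sorted(W[iu][g.adjacency[iu]])
        assert kept == sorted(W[iu])[-4:]

    def test_zero_edge_sparsity_warns_empty(self):
        W = np.ones((5, 5))
        with pytest.warns(UserWarning, match="0 of"):
            g = threshold_by_sparsity(W, 0.05)
        assert g.n_edges == 0

    def test_invalid_sparsity_rejected(self):
        with pytest.raises(ValueError, match="sparsity"):
            threshold_by_sparsity(np.ones((4, 4)), 1.5)

    @given(st.integers(0, 1000))
    def test_edge_sets_nested_across_grid(self, seed):
        rng = np.random.default_rng(seed)
        W = rng.random((12, 12))
        W = (W + W.T) / 2
        prev = np.zeros((12, 12), dtype=bool)
        for s in sparsity_grid(0.05, 0.40, 0.05):
            adj = threshold_by_sparsity(W, s).adjacency
            assert np.all(prev <= adj)
            prev = adj

    def test_tie_break_is_deterministic_row_major(self):
        W = np.ones((4, 4))  # all weights tied
        np.fill_diagonal(W, 0)
        g = threshold_by_sparsity(W, 0.4)  # floor(0.4*6) = 2 edges
        assert [(0, 1), (0, 2)] == [tuple(e) for e in g.edge_list()]


class TestGlobalMetrics:
    def test_triangle(self):
        gm = global_metrics(graph([(0, 1), (1, 2), (0, 2)], 3))
        assert gm == {"Cp": 1.0, "Lp": 1.0, "Eglob": 1.0, "Eloc": 1.0}

    def test_path_graph(self):
        gm = global_metrics(graph([(0, 1), (1, 2)], 3))
        assert gm["Cp"] == 0.0
        assert gm["Lp"] == pytest.approx(4 / 3)
        assert gm["Eglob"] == pytest.approx(5 / 6)

    def test_two_disjoint_edges(self):
        gm = global_metrics(graph([(0, 1), (2, 3)], 4))
        assert gm["Eglob"] == pytest.approx(1 / 3)  # 4 reachable ordered pairs of 12
        assert gm["Lp"] == 1.0  # unreachable pairs excluded

    def test_empty_graph_zeros_with_warning(self):
        with pytest.warns(UserWarning, match="empty graph"):
            gm = global_metrics(graph([], 4))
        assert set(gm.values()) == {0.0}

    @pytest.mark.parametrize("seed", range(6))
    def test_agreement_with_floyd_warshall_oracle(self, seed):
        g = random_graph(np.random.default_rng(seed).integers(5, 16), 0.3, seed)
        D = floyd_warshall(g.adjacency)
        off = ~np.eye(g.n_nodes, dtype=bool)
        finite = np.isfinite(D) & off
        gm = global_metrics(g)
        if finite.any():
            assert gm["Lp"] == pytest.approx(D[finite].mean(), abs=1e-12)
        inv = np.where(np.isfinite(D) & off, 1.0 / np.where(D > 0, D, 1), 0.0)
        assert gm["Eglob"] == pytest.approx(inv[off].sum() / (g.n_nodes * (g.n_nodes - 1)), abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_clustering_matches_networkx(self, seed):
        g = random_graph(12, 0.35, seed + 50)
        gm = global_metrics(g)
        assert gm["Cp"] == pytest.approx(nx.average_clustering(nx.from_numpy_array(g.adjacency)), abs=1e-12)
        assert gm["Eloc"] == pytest.approx(nx.local_efficiency(nx.from_numpy_array(g.adjacency)), abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_adding_an_edge_never_decreases_eglob(self, seed):
        g = random_graph(10, 0.25, seed + 9)
        base = global_metrics(g)["Eglob"]
        adj = g.adjacency.copy()
        missing = np.argwhere(np.triu(~adj, k=1))
        i, j = missing[seed % len(missing)]
        adj[i, j] = adj[j, i] = True
        assert global_metrics(BinaryGraph(adjacency=adj))["Eglob"] >= base

    @pytest.mark.parametrize("seed", range(3))
    def test_metric_bounds(self, seed):
        g = random_graph(14, 0.3, seed + 77)
        gm = global_metrics(g)
        nm = nodal_metrics(g)
        assert 0.0 <= gm["Cp"] <= 1.0 and 0.0 <= gm["Eloc"] <= 1.0
        assert gm["Eglob"] <= 1.0
        assert np.all((nm["nodal_betweenness"] >= 0) & (nm["nodal_betweenness"] <= 1))


class TestNodalMetrics:
    def test_path_graph_betweenness(self):
        nm = nodal_metrics(graph([(0, 1), (1, 2)], 3))
        assert list(nm["nodal_betweenness"]) == [0.0, 1.0, 0.0]

    def test_triangle(self):
        nm = nodal_metrics(graph([(0, 1), (1, 2), (0, 2)], 3))
        assert list(nm["nodal_degree"]) == [2, 2, 2]
        assert list(nm["nodal_betweenness"]) == [0.0, 0.0, 0.0]
        assert list(nm["nodal_efficiency"]) == [1.0, 1.0, 1.0]

    def test_isolated_node(self):
        nm = nodal_metrics(graph([(0, 1)], 3))
        assert nm["nodal_degree"][2] == 0
        assert nm["nodal_efficiency"][2] == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_betweenness_matches_path_counting_oracle(self, seed):
        g = random_graph(8, 0.35, seed + 200)
        nm = nodal_metrics(g)
        assert nm["nodal_betweenness"] == pytest.approx(brute_betweenness(g.adjacency), abs=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_nodal_efficiency_matches_floyd_warshall(self, seed):
        g = random_graph(11, 0.3, seed + 300)
        D = floyd_warshall(g.adjacency)
        inv = np.where(np.isfinite(D) & (D > 0), 1.0 / np.where(D > 0, D, 1), 0.0)
        assert nodal_metrics(g)["nodal_efficiency"] == pytest.approx(
            inv.sum(axis=1) / (g.n_nodes - 1), abs=1e-12
        )


class TestRandomReference:
    @pytest.mark.parametrize("seed", range(3))
    def test_degree_sequence_preserved(self, seed):
        g = random_graph(20, 0.2, seed + 400)
        for null in random_reference(g, n_nulls=5, seed=seed):
            assert np.array_equal(null.degrees, g.degrees)
            assert not np.any(np.diag(null.adjacency))

    def test_triangle_is_rigid(self):
        g = graph([(0, 1), (1, 2), (0, 2)], 3)
        for null in random_reference(g, n_nulls=5, seed=1):
            assert np.array_equal(null.adjacency, g.adjacency)

    def test_same_seed_same_nulls(self):
        g = random_graph(15, 0.3, 9)
        a = random_reference(g, n_nulls=4, seed=5)
        b = random_reference(g, n_nulls=4, seed=5)
        assert all(np.array_equal(x.adjacency, y.adjacency) for x, y in zip(a, b))

    def test_rewiring_actually_changes_the_graph(self):
        g = random_graph(20, 0.3, 3)
        nulls = random_reference(g, n_nulls=3, seed=0)
        assert any(not np.array_equal(n.adjacency, g.adjacency) for n in nulls)


class TestSmallWorld:
    def test_rigid_triangle_gives_unit_indices(self):
        g = graph([(0, 1), (1, 2), (0, 2)], 3)
        swi = small_world_indices(g, random_reference(g, n_nulls=10, seed=0))
        assert swi == {"gamma": 1.0, "lambda": 1.0, "sigma": 1.0}

    def test_zero_null_clustering_is_an_error(self):
        star = graph([(0, i) for i in range(1, 6)], 6)  # stars are rigid, Cp = 0
        with pytest.raises(ValueError, match="gamma undefined"):
            small_world_indices(star, random_reference(star, n_nulls=5, seed=0))

    def test_lattice_with_shortcuts_is_small_world(self):
        # Watts-Strogatz-like: ring lattice (k=4) plus a few shortcuts
        n = 30
        edges = [(i, (i + d) % n) for i in range(n) for d in (1, 2)]
        edges += [(0, 15), (5, 20), (10, 25)]
        g = graph(edges, n)
        swi = small_world_indices(g, random_reference(g, n_nulls=30, seed=2))
        assert swi["gamma"] > 1.5
        assert swi["lambda"] < 2.0


class TestAUC:
    def test_constant_curve_is_rectangle(self):
        grid = sparsity_grid()
        assert auc_over_sparsity((grid, np.full(36, 3.0))) == pytest.approx(0.35 * 3.0)

    def test_linear_ramp(self):
        grid = sparsity_grid()
        assert auc_over_sparsity((grid, np.linspace(0, 1, 36))) == pytest.approx(0.175)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError, match="2 grid points"):
            auc_over_sparsity((np.array([0.1]), np.array([1.0])))

    def test_matches_trapezoid_identity(self, rng):
        grid = sparsity_grid()
        v = rng.normal(size=36)
        manual = np.sum((v[1:] + v[:-1]) / 2 * np.diff(grid))
        assert auc_over_sparsity((grid, v)) == pytest.approx(manual, abs=1e-12)

    def test_nodal_curve_gives_vector(self, rng):
        grid = sparsity_grid()
        v = rng.normal(size=(36, 5))
        out = auc_over_sparsity(MetricCurve("nodal_degree", grid, v))
        assert out.shape == (5,)

    def test_decreasing_grid_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            MetricCurve("Cp", np.array([0.4, 0.05]), np.zeros(2))


class TestSweep:
    def test_returns_all_curves_with_consistent_shapes(self, rng):
        W = rng.random((20, 20))
        W = (W + W.T) / 2
        grid = sparsity_grid(0.1, 0.3, 0.05)
        curves = sweep_metrics(W, grid, n_nulls=5, seed=0)
        assert set(curves) == {
            "Cp", "Lp", "Eglob", "Eloc", "gamma", "lambda", "sigma",
            "nodal_degree", "nodal_betweenness", "nodal_efficiency",
        }
        assert curves["Cp"].values.shape == (5,)
        assert curves["nodal_degree"].values.shape == (5, 20)
        assert curves["Cp"].auc == pytest.approx(
            np.trapezoid(curves["Cp"].values, grid)
        )
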