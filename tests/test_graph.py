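"""Graph construction and metrics, checked against brute-force oracles."""

from collections import deque
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rsntopo.graph import (BinaryGraph, CorrelationMatrix, GraphError,
                           analysis_threshold, clustering_coefficients,
                           correlation_matrix, critical_r, equalize_nodes,
                           graph_metrics, grid_ceil, min_threshold,
                           path_length, threshold_graph, threshold_grid)
from rsntopo.preprocess import VoxelTimeSeriesSet


def _ts(data, tr=2.0):
    data = np.asarray(data, float)
    return VoxelTimeSeriesSet(network="X", subject_id="s",
                              voxel_ids=np.arange(data.shape[0] * 3)
                              .reshape(-1, 3), data=data, tr=tr,
                              regressed=True, filtered=True)


def _graph(adj):
    adj = np.asarray(adj, bool)
    return BinaryGraph(adjacency=adj, threshold=0.5)


# --- brute-force oracles -------------------------------------------------

def oracle_clustering(adj):
    n = len(adj)
    out = np.zeros(n)
    for i in range(n):
        nb = [j for j in range(n) if adj[i][j]]
        k = len(nb)
        if k < 2:
            continue
        links = sum(1 for a, b in combinations(nb, 2) if adj[a][b])
        out[i] = 2 * links / (k * (k - 1))
    return out


def oracle_path_length(adj):
    """Mean BFS distance over pairs of the largest component."""
    n = len(adj)
    seen_global, comps = set(), []
    for s in range(n):
        if s in seen_global:
            continue
        comp = {s}
        q = deque([s])
        while q:
            u = q.popleft()
            for v in range(n):
                if adj[u][v] and v not in comp:
                    comp.add(v)
                    q.append(v)
        seen_global |= comp
        comps.append(sorted(comp))
    big = max(comps, key=len)
    dsum = cnt = 0
    for s in big:
        dist = {s: 0}
        q = deque([s])
        while q:
            u = q.popleft()
            for v in range(n):
                if adj[u][v] and v not in dist:
                    dist[v] = dist[u] + 1
                    q.append(v)
        dsum += sum(dist.values())
        cnt += len(dist) - 1
    return dsum / cnt, len(big) / n


# --- correlation ----------------------------------------------------------

class TestCorrelationMatrix:
    # 3 voxels × 6 timepoints, fixed printed fixture
    FIX = np.array([
        [1.0, 2.0, 0.5, -1.0, 0.3, 1.2],
        [0.9, 1.7, 0.8, -0.7, 0.1, 1.5],
        [-0.2, 0.4, 2.0, 0.6, -1.1, 0.0],
    ])

    def test_matches_covariance_oracle(self):
        r = correlation_matrix(_ts(self.FIX)).r
        for i, j in combinations(range(3), 2):
            x, y = self.FIX[i], self.FIX[j]
            xc, yc = x - x.mean(), y - y.mean()
            expect = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
            assert r[i, j] == pytest.approx(expect, abs=1e-12)
        assert np.allclose(r, r.T, atol=1e-12)
        assert np.allclose(np.diag(r), 1.0)

    def test_duplicated_rows_give_unit_r(self):
        data = np.vstack([self.FIX[0], self.FIX[0]])
        r = correlation_matrix(_ts(data)).r
        assert r[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_negated_row_gives_minus_one(self):
        data = np.vstack([self.FIX[0], -self.FIX[0]])
        r = correlation_matrix(_ts(data)).r
        assert r[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_constant_row_reports_voxel(self):
        data = np.vstack([self.FIX[0], np.full(6, 2.0)])
        with pytest.raises(GraphError, match="constant voxel"):
            correlation_matrix(_ts(data))


class TestThresholding:
    def _corr(self, r):
        return CorrelationMatrix(network="X", subject_id="s",
                                 r=np.asarray(r, float), n_timepoints=50)

    def test_strict_comparison_around_edge(self):
        r = np.array([[1.0, 0.3], [0.3, 1.0]])
        assert threshold_graph(self._corr(r), 0.25).n_edges == 1
        assert threshold_graph(self._corr(r), 0.35).n_edges == 0
        assert threshold_graph(self._corr(r), 0.3).n_edges == 0  # strict >

    def test_high_threshold_empty(self, rng):
        r = np.clip(rng.uniform(-0.9, 0.9, (8, 8)), -0.9, 0.9)
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        g = threshold_graph(self._corr(r), 0.95)
        assert g.n_edges == 0

    @given(st.integers(0, 1000))
    @settings(max_examples=30, deadline=None)
    def test_edge_count_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        r = rng.uniform(-1, 1, (10, 10))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        T = float(rng.uniform(0.05, 0.9))
        g = threshold_graph(self._corr(r), T)
        brute = sum(1 for i, j in combinations(range(10), 2) if r[i, j] > T)
        assert g.n_edges == brute

    @given(st.integers(0, 1000))
    @settings(max_examples=20, deadline=None)
    def test_edges_non_increasing_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        r = rng.uniform(-1, 1, (12, 12))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        counts = [threshold_graph(self._corr(r), float(T)).n_edges
                  for T in threshold_grid()]
        assert np.all(np.diff(counts) <= 0)

    def test_absolute_mode_includes_negative_r(self):
        r = np.array([[1.0, -0.6], [-0.6, 1.0]])
        assert threshold_graph(self._corr(r), 0.5).n_edges == 0
        assert threshold_graph(self._corr(r), 0.5, absolute=True).n_edges == 1


class TestMetrics:
    def test_triangle(self):
        adj = ~np.eye(3, dtype=bool)
        m = graph_metrics(_graph(adj))
        assert m.clustering == 1.0
        assert m.path_length == 1.0

    def test_three_node_path(self):
        adj = np.zeros((3, 3), bool)
        adj[0, 1] = adj[1, 0] = adj[1, 2] = adj[2, 1] = True
        m = graph_metrics(_graph(adj))
        assert m.clustering == 0.0
        assert m.path_length == pytest.approx(4 / 3)

    def test_five_cycle(self):
        adj = np.zeros((5, 5), bool)
        for i in range(5):
            adj[i, (i + 1) % 5] = adj[(i + 1) % 5, i] = True
        m = graph_metrics(_graph(adj))
        assert m.path_length == pytest.approx(1.5)
        assert m.clustering == 0.0

    def test_oracle_equivalence_on_random_graphs(self):
        rng = np.random.default_rng(2024)
        checked = 0
        while checked < 200:
            n = int(rng.integers(4, 31))
            p = float(rng.uniform(0.05, 0.7))
            a = np.triu(rng.random((n, n)) < p, 1)
            adj = a | a.T
            if not adj.any():
                continue
            g = _graph(adj)
            c = clustering_coefficients(adj)
            assert np.allclose(c, oracle_clustering(adj), atol=1e-12)
            L, frac = path_length(g)
            Lo, fo = oracle_path_length(adj)
            if fo * n < 2:
                continue
            assert L == pytest.approx(Lo, abs=1e-12)
            assert frac == pytest.approx(fo, abs=1e-12)
            checked += 1

    def test_edgeless_graph_rejected(self):
        with pytest.raises(GraphError, match="no paths"):
            path_length(_graph(np.zeros((4, 4), bool)))

    def test_degrees_match_neighbor_counts(self, rng):
        a = np.triu(rng.random((20, 20)) < 0.3, 1)
        adj = a | a.T
        g = _graph(adj)
        assert np.array_equal(g.degrees(), adj.sum(1))


class TestThresholdRules:
    def test_grid_is_exactly_18_values(self):
        grid = threshold_grid()
        assert len(grid) == 18
        assert grid[0] == 0.125 and grid[-1] == 0.55
        assert np.allclose(np.diff(grid), 0.025)

    def test_min_threshold_at_248_df(self):
        # two-sided p = 0.05 at df = 248 → r ≈ 0.124 → grid value 0.125
        assert critical_r(0.05, 248) == pytest.approx(0.1241, abs=5e-4)
        assert min_threshold(248) == 0.125

    def test_analysis_threshold_bonferroni(self):
        # ~250-voxel network: alpha/n_pairs pushes critical r near 0.3
        t = analysis_threshold(250 * 249 // 2, 248)
        assert t in threshold_grid()
        assert t >= critical_r(0.05 / (250 * 249 // 2), 248)

    def test_grid_ceil_out_of_range_raises(self):
        with pytest.raises(GraphError):
            grid_ceil(0.9)


class TestEqualizeNodes:
    def test_min_rule_and_subset(self):
        sets = {"A": np.arange(50), "B": np.arange(30), "C": np.arange(40)}
        draws = equalize_nodes(sets, seed=4, n_draws=5)
        assert len(draws) == 5
        for draw in draws:
            for name, sub in draw.items():
                assert len(sub) == 30
                assert set(sub).issubset(set(sets[name]))
                assert len(set(sub)) == len(sub)

    def test_reproducible_with_seed(self):
        sets = {"A": np.arange(20), "B": np.arange(15)}
        d1 = equalize_nodes(sets, seed=9, n_draws=3)
        d2 = equalize_nodes(sets, seed=9, n_draws=3)
        for a, b in zip(d1, d2):
            assert all(np.array_equal(a[k], b[k]) for k in a)

    def test_single_network_rejected(self):
        with pytest.raises(GraphError):
            equalize_nodes({"A": np.arange(5)}, seed=0)
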