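"""Correlation graphs and their topology.

A network's voxel×voxel Pearson matrix is thresholded at T (signed r > T)
into an undirected binary graph; clustering coefficient and characteristic
path length are computed on dense boolean adjacency with numpy/scipy.
Path length follows the largest-connected-component rule; the maximum grid
threshold is chosen so the largest component still covers ≥ 90% of voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .preprocess import VoxelTimeSeriesSet

__all__ = [
    "CorrelationMatrix",
    "BinaryGraph",
    "GraphMetrics",
    "correlation_matrix",
    "threshold_graph",
    "clustering_coefficients",
    "path_length",
    "graph_metrics",
    "threshold_grid",
    "critical_r",
    "grid_ceil",
    "min_threshold",
    "analysis_threshold",
    "equalize_nodes",
]

#: The canonical threshold sweep: 0.125 ≤ T ≤ 0.55, step 0.025 (18 values).
GRID_MIN, GRID_MAX, GRID_STEP = 0.125, 0.55, 0.025


class GraphError(ValueError):
    pass


@dataclass
class CorrelationMatrix:
    network: str
    subject_id: str
    r: np.ndarray                # (N, N) symmetric, unit diagonal
    n_timepoints: int

    @property
    def n_nodes(self) -> int:
        return self.r.shape[0]


@dataclass
class BinaryGraph:
    adjacency: np.ndarray        # (N, N) bool, symmetric, zero diagonal
    threshold: float
    network: str = ""
    subject_id: str = ""

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.adjacency, 1).sum())

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(np.int64)


@dataclass
class GraphMetrics:
    n_nodes: int
    n_edges: int
    degrees: np.ndarray = field(repr=False)
    clustering_per_node: np.ndarray = field(repr=False)
    clustering: float            # mean C over ALL nodes
    path_length: float           # mean shortest path on largest component
    largest_component_fraction: float


def correlation_matrix(ts: VoxelTimeSeriesSet) -> CorrelationMatrix:
    """Pearson correlation between all voxel pairs of a cleaned set."""
    if ts.n_timepoints < 3:
        raise GraphError("need ≥ 3 timepoints for correlation")
    sd = ts.data.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        ids = [tuple(v) for v in np.atleast_2d(ts.voxel_ids)[bad[:10]]]
        raise GraphError(f"constant voxel time-series at {ids}")
    r = np.corrcoef(ts.data)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(network=ts.network, subject_id=ts.subject_id,
                             r=r, n_timepoints=ts.n_timepoints)


def threshold_graph(corr: CorrelationMatrix, threshold: float,
                    absolute: bool = False) -> BinaryGraph:
    """Edge iff r[i, j] > T (strict), i ≠ j.  ``absolute=True`` thresholds
    |r| instead of signed r."""
    if not 0 < threshold < 1:
        raise GraphError("threshold must lie in (0, 1)")
    r = np.abs(corr.r) if absolute else corr.r
    adj = r > threshold
    np.fill_diagonal(adj, False)
    adj &= adj.T  # defensive: r is symmetric, keep adjacency exactly so
    return BinaryGraph(adjacency=adj, threshold=threshold,
                       network=corr.network, subject_id=corr.subject_id)


def clustering_coefficients(adj: np.ndarray) -> np.ndarray:
    """Per-node clustering: C_i = 2·t_i / (k_i (k_i − 1)), with t_i the
    number of edges among i's neighbours; nodes of degree < 2 get 0."""
    a = adj.astype(np.float64)
    deg = a.sum(axis=1)
    # (A @ A * A).sum(1)[i] counts closed 2-paths through i = 2·t_i
    tri2 = ((a @ a) * a).sum(axis=1)
    denom = deg * (deg - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, tri2 / denom, 0.0)
    return c


def _mean_distance_connected(adj: np.ndarray) -> float:
    """Mean unweighted shortest-path distance over all unordered pairs of
    a connected graph, by breadth-first reachability expansion:
    R_k = R_{k-1} ∪ (R_{k-1}·A); pairs first reached at step k are at
    distance k.  Equivalent to all-pairs BFS, but runs as dense float32
    matmuls, which is fast for the small, dense, low-diameter graphs this
    pipeline produces."""
    n = adj.shape[0]
    a = adj.astype(np.float32)
    reach = adj | np.eye(n, dtype=bool)
    n_prev = int(reach.sum())
    dist_total = int(adj.sum())          # ordered pairs at distance 1
    k = 1
    while n_prev < n * n:
        k += 1
        reach_new = reach | ((reach.astype(np.float32) @ a) > 0)
        n_new = int(reach_new.sum())
        if n_new == n_prev:              # should not happen when connected
            raise GraphError("graph is not connected")
        dist_total += k * (n_new - n_prev)
        reach, n_prev = reach_new, n_new
    return dist_total / (n * (n - 1))


def path_length(g: BinaryGraph) -> tuple[float, float]:
    """(L, largest-component fraction): mean BFS distance over all
    unordered pairs inside the largest connected component."""
    adj = g.adjacency
    if not adj.any():
        raise GraphError("no paths: graph has no edges")
    n = g.n_nodes
    ncomp, labels = connected_components(csr_matrix(adj), directed=False)
    sizes = np.bincount(labels)
    big = int(np.argmax(sizes))
    members = np.flatnonzero(labels == big)
    frac = len(members) / n
    if len(members) < 2:
        raise GraphError("largest component has < 2 nodes")
    sub = adj[np.ix_(members, members)]
    return _mean_distance_connected(sub), float(frac)


def graph_metrics(g: BinaryGraph) -> GraphMetrics:
    c_i = clustering_coefficients(g.adjacency)
    L, frac = path_length(g)
    return GraphMetrics(
        n_nodes=g.n_nodes, n_edges=g.n_edges, degrees=g.degrees(),
        clustering_per_node=c_i, clustering=float(c_i.mean()),
        path_length=L, largest_component_fraction=frac,
    )


def threshold_grid() -> np.ndarray:
    """Exactly {0.125, 0.150, …, 0.550}."""
    n = int(round((GRID_MAX - GRID_MIN) / GRID_STEP)) + 1
    return np.round(GRID_MIN + GRID_STEP * np.arange(n), 3)


def critical_r(alpha: float, df: int) -> float:
    """Two-sided critical Pearson r at significance ``alpha`` with ``df``
    degrees of freedom (df = t − 2)."""
    if df < 1:
        raise GraphError("df must be ≥ 1")
    t_crit = sstats.t.ppf(1 - alpha / 2, df)
    return float(t_crit / np.sqrt(t_crit**2 + df))


def grid_ceil(r: float, grid: np.ndarray | None = None) -> float:
    """Smallest grid threshold ≥ r."""
    grid = threshold_grid() if grid is None else np.asarray(grid)
    above = grid[grid >= r - 1e-12]
    if above.size == 0:
        raise GraphError(f"critical r {r:.3f} exceeds the threshold grid")
    return float(above[0])


def min_threshold(df: int, alpha: float = 0.05) -> float:
    """Lower end of the sweep: the critical r for uncorrected p < alpha,
    rounded up to the grid."""
    return grid_ceil(critical_r(alpha, df))


def analysis_threshold(n_pairs: int, df: int, alpha: float = 0.05) -> float:
    """Conservative single threshold for detailed analysis: critical r at
    the Bonferroni-corrected level alpha / n_pairs (n_pairs = voxel pairs
    of the largest network), rounded up to the grid."""
    if n_pairs < 1:
        raise GraphError("n_pairs must be ≥ 1")
    return grid_ceil(critical_r(alpha / n_pairs, df))


def equalize_nodes(voxel_sets: dict[str, np.ndarray], seed: int,
                   n_draws: int = 10) -> list[dict[str, np.ndarray]]:
    """Subsample every network to the smallest network's node count.

    Returns ``n_draws`` independent draws; each network's subset is a
    uniform random sample without replacement of its original voxels.
    Downstream metrics are averaged over draws.
    """
    if len(voxel_sets) < 2:
        raise GraphError("node equalization needs ≥ 2 networks")
    target = min(len(v) for v in voxel_sets.values())
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(n_draws):
        draw = {}
        for name, vox in voxel_sets.items():
            idx = np.sort(rng.choice(len(vox), size=target, replace=False))
            draw[name] = np.asarray(vox)[idx]
        draws.append(draw)
    return draws
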