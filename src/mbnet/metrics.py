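"""Sparsity-thresholded graph metrics and their AUC over the sparsity grid.

Each subject's weighted similarity matrix is binarised at a sweep of sparsity
levels S (fraction of the strongest possible edges kept). At every level we
compute the standard connectome metrics:

global   Cp (mean clustering), Lp (characteristic path length), Eglob,
         Eloc, and the null-normalised gamma = Cp/<Cp_null>,
         lambda = Lp/<Lp_null>, sigma = gamma/lambda (small-worldness);
nodal    degree, betweenness centrality, nodal efficiency.

Because no single sparsity is privileged, each metric is summarised by the
trapezoidal area under its curve (AUC) across the grid; group inference
operates on the AUCs.

Metrics are computed directly on boolean adjacency matrices (BFS shortest
paths via :func:`scipy.sparse.csgraph.shortest_path`, triangle counts via
matrix products) so that the degree-preserving null sweep — thousands of
rewired graphs per subject — stays cheap. Betweenness uses networkx's
Brandes algorithm; it is never needed on null graphs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from numba import njit
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "BinaryGraph",
    "MetricCurve",
    "sparsity_grid",
    "threshold_by_sparsity",
    "global_metrics",
    "nodal_metrics",
    "random_reference",
    "small_world_indices",
    "auc_over_sparsity",
    "sweep_metrics",
    "GLOBAL_METRICS",
    "NODAL_METRICS",
]

GLOBAL_METRICS = ("Cp", "Lp", "Eglob", "Eloc", "gamma", "lambda", "sigma")
NODAL_METRICS = ("nodal_degree", "nodal_betweenness", "nodal_efficiency")


@dataclass
class BinaryGraph:
    """Undirected unweighted graph as a symmetric boolean adjacency matrix."""

    adjacency: np.ndarray
    sparsity: float = float("nan")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    def edge_list(self) -> np.ndarray:
        iu = np.triu_indices(self.n_nodes, k=1)
        mask = self.adjacency[iu]
        return np.column_stack((iu[0][mask], iu[1][mask]))


def sparsity_grid(s_min: float = 0.05, s_max: float = 0.40, step: float = 0.01) -> np.ndarray:
    """Closed sparsity grid; defaults give the 36 points 0.05, 0.06, ..., 0.40."""
    n = int(round((s_max - s_min) / step)) + 1
    return np.linspace(s_min, s_max, n)


def threshold_by_sparsity(W, S: float) -> BinaryGraph:
    """Keep the floor(S * R(R-1)/2) strongest off-diagonal weights as edges.

    Ties are broken deterministically by ascending (row, col) index, which
    makes edge sets nested across increasing S. A sparsity too small to
    retain any edge yields an empty graph with a warning, not an error.
    """
    W = np.asarray(getattr(W, "similarity", W), dtype=float)
    if not 0.0 < S < 1.0:
        raise ValueError(f"sparsity must lie in (0, 1), got {S}")
    R = W.shape[0]
    n_possible = R * (R - 1) // 2
    m = int(np.floor(S * n_possible))
    adj = np.zeros((R, R), dtype=bool)
    if m == 0:
        warnings.warn(f"sparsity {S} keeps 0 of {n_possible} edges; empty graph", stacklevel=2)
        return BinaryGraph(adjacency=adj, sparsity=S)
    iu = np.triu_indices(R, k=1)
    w = W[iu]
    order = np.lexsort((iu[1], iu[0], -w))  # primary: weight desc; ties: (row, col) asc
    keep = order[:m]
    adj[iu[0][keep], iu[1][keep]] = True
    adj |= adj.T
    return BinaryGraph(adjacency=adj, sparsity=S)


def _adjacency(g) -> np.ndarray:
    return np.asarray(getattr(g, "adjacency", g), dtype=bool)


def _clustering_per_node(adj: np.ndarray) -> np.ndarray:
    A = adj.astype(np.float64)
    deg = A.sum(axis=1)
    tri = (A @ A * A).sum(axis=1) / 2.0
    denom = deg * (deg - 1) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, tri / np.where(denom > 0, denom, 1.0), 0.0)
    return c


def _distances(adj: np.ndarray) -> np.ndarray:
    return shortest_path(csr_matrix(adj.astype(np.int8)), method="D", unweighted=True)


def _lp_from_distances(D: np.ndarray) -> float:
    off = ~np.eye(D.shape[0], dtype=bool)
    finite = np.isfinite(D) & off
    if not finite.any():
        return 0.0
    return float(D[finite].mean())


def _inverse_distances(D: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        inv = 1.0 / D
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv


def _eglob(adj: np.ndarray, D: np.ndarray | None = None) -> float:
    R = adj.shape[0]
    if R < 2:
        return 0.0
    if D is None:
        D = _distances(adj)
    inv = _inverse_distances(D)
    return float(inv.sum() / (R * (R - 1)))


def global_metrics(g) -> dict:
    """Cp, Lp, Eglob, Eloc of a binary graph.

    Lp averages shortest path lengths over *reachable* ordered pairs only;
    unreachable pairs contribute 1/inf = 0 to Eglob. Nodes with fewer than
    two neighbours contribute 0 to Eloc. An empty graph returns all zeros
    with a warning.
    """
    adj = _adjacency(g)
    R = adj.shape[0]
    if adj.sum() == 0:
        warnings.warn("empty graph: all global metrics set to 0", stacklevel=2)
        return {"Cp": 0.0, "Lp": 0.0, "Eglob": 0.0, "Eloc": 0.0}
    D = _distances(adj)
    cp = float(_clustering_per_node(adj).mean())
    lp = _lp_from_distances(D)
    eglob = _eglob(adj, D)
    eloc = 0.0
    for i in range(R):
        nbrs = np.flatnonzero(adj[i])
        if nbrs.size >= 2:
            eloc += _eglob(adj[np.ix_(nbrs, nbrs)])
    eloc /= R
    return {"Cp": cp, "Lp": lp, "Eglob": eglob, "Eloc": float(eloc)}


def nodal_metrics(g) -> dict:
    """Per-node degree, betweenness centrality and nodal efficiency.

    Betweenness is the fraction of shortest paths between other node pairs
    passing through the node, normalised by (R-1)(R-2)/2. Nodal efficiency
    of node i is the mean of 1/d(i, j) over the other R-1 nodes (0 for
    unreachable j), so isolated nodes score 0.
    """
    adj = _adjacency(g)
    R = adj.shape[0]
    degree = adj.sum(axis=1).astype(float)
    D = _distances(adj)
    inv = _inverse_distances(D)
    efficiency = inv.sum(axis=1) / max(R - 1, 1)
    gnx = nx.from_numpy_array(adj)
    bc = nx.betweenness_centrality(gnx, normalized=True)
    betweenness = np.array([bc[i] for i in range(R)])
    return {
        "nodal_degree": degree,
        "nodal_betweenness": betweenness,
        "nodal_efficiency": efficiency,
    }


@njit(cache=False)
def _ms_rewire(adj, edges, n_attempts, seed):  # pragma: no cover - numba kernel
    np.random.seed(seed)
    m = edges.shape[0]
    for _ in range(n_attempts):
        ei = np.random.randint(m)
        ej = np.random.randint(m)
        if ei == ej:
            continue
        a, b = edges[ei, 0], edges[ei, 1]
        c, d = edges[ej, 0], edges[ej, 1]
        if np.random.randint(2) == 1:
            c, d = d, c
        if a == c or a == d or b == c or b == d:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = False
        adj[b, a] = False
        adj[c, d] = False
        adj[d, c] = False
        adj[a, d] = True
        adj[d, a] = True
        adj[c, b] = True
        adj[b, c] = True
        edges[ei, 0] = a
        edges[ei, 1] = d
        edges[ej, 0] = c
        edges[ej, 1] = b


def random_reference(g, n_nulls: int = 100, seed: int = 0, swap_factor: int = 10) -> list:
    """Degree-preserving (Maslov-Sneppen) rewired null graphs.

    Each null starts from ``g`` and undergoes ``swap_factor * |E|`` attempted
    double-edge swaps; an attempt is applied only if it creates no self-loop
    or multi-edge, so every null has exactly g's degree sequence. Rigid
    graphs (no admissible swap, e.g. a triangle) are returned unchanged.
    Fully deterministic given ``seed``.
    """
    adj0 = _adjacency(g)
    base = BinaryGraph(adjacency=adj0, sparsity=getattr(g, "sparsity", float("nan")))
    edges0 = base.edge_list().astype(np.int64)
    m = edges0.shape[0]
    rng = np.random.default_rng(seed)
    nulls = []
    for _ in range(n_nulls):
        s = int(rng.integers(0, 2**31 - 1))
        if m == 0:
            nulls.append(BinaryGraph(adjacency=adj0.copy(), sparsity=base.sparsity))
            continue
        adj = adj0.copy()
        edges = edges0.copy()
        _ms_rewire(adj, edges, swap_factor * m, s)
        nulls.append(BinaryGraph(adjacency=adj, sparsity=base.sparsity))
    return nulls


def small_world_indices(g, nulls) -> dict:
    """gamma, lambda, sigma of ``g`` against its degree-preserving nulls."""
    adj = _adjacency(g)
    cp = float(_clustering_per_node(adj).mean())
    lp = _lp_from_distances(_distances(adj))
    null_cp = np.empty(len(nulls))
    null_lp = np.empty(len(nulls))
    for k, null in enumerate(nulls):
        a = _adjacency(null)
        null_cp[k] = _clustering_per_node(a).mean()
        null_lp[k] = _lp_from_distances(_distances(a))
    mean_cp = null_cp.mean()
    mean_lp = null_lp.mean()
    if mean_cp == 0:
        raise ValueError("mean null clustering coefficient is 0; gamma undefined")
    if mean_lp == 0:
        raise ValueError("mean null path length is 0; lambda undefined")
    gamma = cp / mean_cp
    lam = lp / mean_lp
    return {"gamma": gamma, "lambda": lam, "sigma": gamma / lam}


@dataclass
class MetricCurve:
    """A metric's value across the sparsity grid plus its AUC summary.

    ``values`` has shape (n_sparsities,) for global metrics or
    (n_sparsities, R) for nodal metrics.
    """

    name: str
    sparsities: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.sparsities = np.asarray(self.sparsities, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.sparsities.ndim != 1 or np.any(np.diff(self.sparsities) <= 0):
            raise ValueError("sparsity grid must be 1-D and strictly increasing")
        if self.values.shape[0] != self.sparsities.shape[0]:
            raise ValueError("values and sparsity grid length mismatch")

    @property
    def auc(self):
        return auc_over_sparsity(self)


def auc_over_sparsity(curve):
    """Trapezoidal area of a metric curve over the sparsity grid.

    Accepts a :class:`MetricCurve` or an ``(sparsities, values)`` pair;
    returns a scalar for global metrics, a length-R vector for nodal ones.
    """
    if isinstance(curve, MetricCurve):
        s, v = curve.sparsities, curve.values
    else:
        s, v = np.asarray(curve[0], dtype=float), np.asarray(curve[1], dtype=float)
    if s.size < 2:
        raise ValueError("AUC needs at least 2 grid points")
    out = np.trapezoid(v, s, axis=0)
    return float(out) if np.ndim(out) == 0 else out


def sweep_metrics(
    W,
    sparsities: np.ndarray | None = None,
    n_nulls: int = 100,
    seed: int = 0,
    small_world: bool = True,
    betweenness: bool = True,
) -> dict:
    """All metric curves of one subject's similarity matrix.

    Returns ``{metric_name: MetricCurve}`` over the sparsity grid. Null
    graphs for gamma/lambda/sigma are regenerated at every sparsity level
    (the degree sequence changes with S); seeds derive deterministically
    from ``seed``.
    """
    if sparsities is None:
        sparsities = sparsity_grid()
    sparsities = np.asarray(sparsities, dtype=float)
    W = np.asarray(getattr(W, "similarity", W), dtype=float)
    R = W.shape[0]
    n_s = sparsities.size

    glob = {name: np.empty(n_s) for name in ("Cp", "Lp", "Eglob", "Eloc")}
    sw = {name: np.empty(n_s) for name in ("gamma", "lambda", "sigma")}
    nodal = {name: np.empty((n_s, R)) for name in NODAL_METRICS}
    if not betweenness:
        nodal.pop("nodal_betweenness")

    seed_rng = np.random.default_rng(seed)
    for k, s in enumerate(sparsities):
        g = threshold_by_sparsity(W, s)
        gm = global_metrics(g)
        for name in glob:
            glob[name][k] = gm[name]
        nm = nodal_metrics(g) if betweenness else _nodal_no_betweenness(g)
        for name in nodal:
            nodal[name][k] = nm[name]
        if small_world:
            nulls = random_reference(g, n_nulls=n_nulls, seed=int(seed_rng.integers(2**31 - 1)))
            try:
                swi = small_world_indices(g, nulls)
            except ValueError as err:
                # e.g. a very sparse graph whose nulls carry no triangles
                warnings.warn(f"S={s:g}: {err}; recording NaN", stacklevel=2)
                swi = {"gamma": np.nan, "lambda": np.nan, "sigma": np.nan}
            for name in sw:
                sw[name][k] = swi[name]

    curves = {name: MetricCurve(name, sparsities, vals) for name, vals in glob.items()}
    if small_world:
        curves.update({name: MetricCurve(name, sparsities, vals) for name, vals in sw.items()})
    curves.update({name: MetricCurve(name, sparsities, vals) for name, vals in nodal.items()})
    return curves


def _nodal_no_betweenness(g) -> dict:
    adj = _adjacency(g)
    R = adj.shape[0]
    D = _distances(adj)
    inv = _inverse_distances(D)
    return {
        "nodal_degree": adj.sum(axis=1).astype(float),
        "nodal_efficiency": inv.sum(axis=1) / max(R - 1, 1),
    }
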