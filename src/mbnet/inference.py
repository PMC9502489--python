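"""Group inference on network metrics and connections.

Three statistical layers, all nonparametric where the sampling distribution
is awkward:

* **AUC permutation tests** — the AUC of each topological metric over the
  sparsity grid is compared between groups by reshuffling group labels and
  recomputing the mean difference; two-tailed p with the (+1)/(n+1)
  correction, plus the null's 2.5th/97.5th percentile critical values.
  Families of nodal tests are corrected with Benjamini-Hochberg FDR.
* **Network-based statistics (NBS)** — edge-wise two-sample t-tests on the
  similarity values; edges below the primary threshold (per contrast
  direction) form connected components whose extent (edge count) is
  referred to the permutation null of the maximum component extent.
* **Partial correlation** — Pearson correlation of OLS residuals after
  regressing out covariates (age and sex in the clinical use case), with a
  t-distribution p on n - 2 - k degrees of freedom.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationTestResult",
    "NBSComponent",
    "NBSResult",
    "PartialCorrelationResult",
    "permutation_test_auc",
    "permutation_test_auc_table",
    "fdr_bh",
    "nbs",
    "partial_correlation",
]


@dataclass
class PermutationTestResult:
    metric: str
    node: str  # region id or "global"
    observed: float  # mean(A) - mean(B)
    n_perm: int
    p: float
    critical_low: float  # 2.5th percentile of the null
    critical_high: float  # 97.5th percentile of the null
    seed: int


def _null_mean_diffs(pooled: np.ndarray, n_first: int, n_perm: int, seed: int) -> np.ndarray:
    """Monte-Carlo null of mean(group1) - mean(group2) under label reshuffles.

    ``pooled`` rows are put in a canonical (lexicographic) order first, so
    the null sample depends only on the pooled multiset and the group
    sizes — never on the order subjects were supplied in.
    """
    pooled = pooled[np.lexsort(pooled.T[::-1])] if pooled.ndim == 2 else np.sort(pooled)
    n = pooled.shape[0]
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm,) + pooled.shape[1:])
    for i in range(n_perm):
        idx = rng.permutation(n)
        null[i] = pooled[idx[:n_first]].mean(axis=0) - pooled[idx[n_first:]].mean(axis=0)
    return null


def permutation_test_auc(
    values_a,
    values_b,
    n_perm: int = 1000,
    seed: int = 0,
    metric: str = "",
    node: str = "global",
) -> PermutationTestResult:
    """Two-tailed label-permutation test of the group mean AUC difference.

    ``observed = mean(values_a) - mean(values_b)``;
    ``p = (#{|null| >= |observed|} + 1) / (n_perm + 1)``. The null sample is
    generated from the pooled values in a canonical order, so swapping the
    two inputs returns the identical p with the observed difference negated.
    """
    a = np.asarray(values_a, dtype=float).ravel()
    b = np.asarray(values_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very low for a permutation test", stacklevel=2)
    observed = float(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    # canonical first-group size: invariant under swapping the two inputs
    if a.size != b.size:
        n_first = min(a.size, b.size)
    else:
        n_first = a.size
    null = _null_mean_diffs(pooled, n_first, n_perm, seed)
    p = float((np.sum(np.abs(null) >= abs(observed)) + 1) / (n_perm + 1))
    lo, hi = np.percentile(null, [2.5, 97.5])
    return PermutationTestResult(
        metric=metric,
        node=node,
        observed=observed,
        n_perm=n_perm,
        p=p,
        critical_low=float(lo),
        critical_high=float(hi),
        seed=seed,
    )


def permutation_test_auc_table(
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    metric: str = "",
    nodes=None,
) -> list:
    """Column-wise permutation tests sharing one set of label reshuffles.

    ``values_a`` is (n_a, K), ``values_b`` is (n_b, K): one column per node.
    Sharing the permutations across columns is the standard way to test a
    family of nodal AUCs; multiplicity is handled afterwards by
    :func:`fdr_bh`.
    """
    A = np.atleast_2d(np.asarray(values_a, dtype=float))
    B = np.atleast_2d(np.asarray(values_b, dtype=float))
    if A.shape[0] == 0 or B.shape[0] == 0:
        raise ValueError("both groups must be non-empty")
    if A.shape[1] != B.shape[1]:
        raise ValueError("groups disagree on the number of columns")
    K = A.shape[1]
    if nodes is None:
        nodes = [str(k + 1) for k in range(K)]
    observed = A.mean(axis=0) - B.mean(axis=0)
    pooled = np.vstack([A, B])
    null = _null_mean_diffs(pooled, A.shape[0], n_perm, seed)  # (n_perm, K)
    counts = np.sum(np.abs(null) >= np.abs(observed)[None, :], axis=0)
    pvals = (counts + 1) / (n_perm + 1)
    lo, hi = np.percentile(null, [2.5, 97.5], axis=0)
    return [
        PermutationTestResult(
            metric=metric,
            node=str(nodes[k]),
            observed=float(observed[k]),
            n_perm=n_perm,
            p=float(pvals[k]),
            critical_low=float(lo[k]),
            critical_high=float(hi[k]),
            seed=seed,
        )
        for k in range(K)
    ]


def fdr_bh(pvals, q: float = 0.05):
    """Benjamini-Hochberg step-up FDR: (reject flags, adjusted p-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    reject, padj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, padj


# ---------------------------------------------------------------------------
# network-based statistics


@dataclass
class NBSComponent:
    nodes: list  # region ids
    edges: list  # (region_i, region_j) tuples, i < j in matrix order
    extent: int  # edge count
    p: float


@dataclass
class NBSResult:
    direction: str  # "A>B" or "B>A"
    primary_p: float
    components: list  # NBSComponent, sorted by decreasing extent
    n_perm: int
    seed: int
    node_subset: list
    null_max_extent: np.ndarray = field(repr=False, default=None)
    edge_t: np.ndarray = field(repr=False, default=None)  # (n_nodes, n_nodes)
    edge_p: np.ndarray = field(repr=False, default=None)

    @property
    def significant(self) -> list:
        return [c for c in self.components if c.p < 0.05]


def _stack_edges(mats, subset_idx):
    rows = []
    for m in mats:
        W = np.asarray(getattr(m, "similarity", m), dtype=float)
        W = W[np.ix_(subset_idx, subset_idx)]
        iu = np.triu_indices(len(subset_idx), k=1)
        rows.append(W[iu])
    return np.vstack(rows)


def _t_stats(X, labels_first, n1, n2):
    """Equal-variance two-sample t per column; labels_first is a boolean row mask."""
    g1 = X[labels_first]
    g2 = X[~labels_first]
    m1, m2 = g1.mean(axis=0), g2.mean(axis=0)
    v1, v2 = g1.var(axis=0, ddof=1), g2.var(axis=0, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t[~np.isfinite(t)] = 0.0
    return t


def _max_component_extent(supra: np.ndarray, n_nodes: int, iu) -> int:
    if not supra.any():
        return 0
    adj = np.zeros((n_nodes, n_nodes), dtype=bool)
    adj[iu[0][supra], iu[1][supra]] = True
    adj |= adj.T
    n_comp, memb = connected_components(csr_matrix(adj), directed=False)
    counts = np.zeros(n_comp, dtype=int)
    comp_of_edge = memb[iu[0][supra]]
    np.add.at(counts, comp_of_edge, 1)
    return int(counts.max())


def _components(supra: np.ndarray, region_ids, iu, null_max, n_perm):
    n_nodes = len(region_ids)
    comps = []
    if supra.any():
        adj = np.zeros((n_nodes, n_nodes), dtype=bool)
        adj[iu[0][supra], iu[1][supra]] = True
        adj |= adj.T
        _, memb = connected_components(csr_matrix(adj), directed=False)
        for c in np.unique(memb[iu[0][supra]]):
            sel = supra & (memb[iu[0]] == c)
            edges = [(region_ids[i], region_ids[j]) for i, j in zip(iu[0][sel], iu[1][sel])]
            nodes = sorted({n for e in edges for n in e}, key=lambda x: str(x))
            extent = int(sel.sum())
            p = float((np.sum(null_max >= extent) + 1) / (n_perm + 1))
            comps.append(NBSComponent(nodes=nodes, edges=edges, extent=extent, p=p))
    comps.sort(key=lambda c: -c.extent)
    return comps


def nbs(
    matrices_a,
    matrices_b,
    primary_p: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    node_subset=None,
) -> dict:
    """Network-based statistics on two groups of similarity matrices.

    Edge-wise equal-variance t-tests over ``node_subset`` (default: all
    regions); per direction, edges with two-sided p < ``primary_p`` and the
    matching t-sign form connected components, whose extents are referred to
    the permutation null of the maximum suprathreshold component extent.
    Returns ``{"A>B": NBSResult, "B>A": NBSResult}``. An empty
    suprathreshold set gives a result with zero components.
    """
    if len(matrices_a) < 2 or len(matrices_b) < 2:
        raise ValueError("NBS needs at least 2 subjects per group")
    first = matrices_a[0]
    region_ids = list(getattr(first, "region_ids", [])) or list(
        range(1, np.asarray(getattr(first, "similarity", first)).shape[0] + 1)
    )
    if node_subset is None:
        subset_idx = np.arange(len(region_ids))
    else:
        wanted = list(node_subset)
        missing = [w for w in wanted if w not in region_ids]
        if missing:
            raise ValueError(f"node_subset entries not among regions: {missing}")
        subset_idx = np.array([region_ids.index(w) for w in wanted])
    sub_ids = [region_ids[i] for i in subset_idx]
    n_nodes = len(sub_ids)
    iu = np.triu_indices(n_nodes, k=1)

    A = _stack_edges(matrices_a, subset_idx)
    B = _stack_edges(matrices_b, subset_idx)
    n1, n2 = A.shape[0], B.shape[0]
    df = n1 + n2 - 2
    t_crit = stats.t.ppf(1.0 - primary_p / 2.0, df)

    X_obs = np.vstack([A, B])
    lab_obs = np.zeros(n1 + n2, dtype=bool)
    lab_obs[:n1] = True
    t_obs = _t_stats(X_obs, lab_obs, n1, n2)
    p_obs = 2.0 * stats.t.sf(np.abs(t_obs), df)

    # canonical row order: the null must not depend on subject ordering
    X = X_obs[np.lexsort(X_obs.T[::-1])]
    rng = np.random.default_rng(seed)
    null_pos = np.empty(n_perm)
    null_neg = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.permutation(n1 + n2)
        lab = np.zeros(n1 + n2, dtype=bool)
        lab[idx[:n1]] = True
        t = _t_stats(X, lab, n1, n2)
        null_pos[i] = _max_component_extent(t > t_crit, n_nodes, iu)
        null_neg[i] = _max_component_extent(t < -t_crit, n_nodes, iu)

    t_mat = np.zeros((n_nodes, n_nodes))
    p_mat = np.ones((n_nodes, n_nodes))
    t_mat[iu] = t_obs
    t_mat += t_mat.T
    p_mat[iu] = p_obs
    p_mat = np.minimum(p_mat, p_mat.T)
    np.fill_diagonal(p_mat, 1.0)

    out = {}
    for direction, supra, null_max in (
        ("A>B", (t_obs > 0) & (p_obs < primary_p), null_pos),
        ("B>A", (t_obs < 0) & (p_obs < primary_p), null_neg),
    ):
        out[direction] = NBSResult(
            direction=direction,
            primary_p=primary_p,
            components=_components(supra, sub_ids, iu, null_max, n_perm),
            n_perm=n_perm,
            seed=seed,
            node_subset=sub_ids,
            null_max_extent=null_max,
            edge_t=t_mat,
            edge_p=p_mat,
        )
    return out


# ---------------------------------------------------------------------------
# partial correlation


@dataclass
class PartialCorrelationResult:
    x_name: str
    y_name: str
    covariates: list
    n: int  # subjects actually used (after pairwise deletion)
    r: float
    p: float
    fdr_q: float | None = None  # BH-adjusted p when part of a family
    significant: bool | None = None


def partial_correlation(
    x,
    y,
    covariates=None,
    x_name: str = "x",
    y_name: str = "y",
    covariate_names=None,
) -> PartialCorrelationResult:
    """Partial Pearson correlation of ``x`` and ``y`` given covariates.

    Residualises both variables on the covariates (plus intercept) by OLS
    and correlates the residuals; p comes from the t-distribution with
    ``n - 2 - k`` degrees of freedom. With no covariates this reduces to the
    plain Pearson correlation. Rows with a missing value in x, y or any
    covariate are dropped pairwise (logged). If either residual is
    essentially constant — e.g. y *is* one of the covariates — the
    correlation is reported as 0 with a warning rather than as noise.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if covariates is None:
        C = np.empty((x.size, 0))
        cov_names = []
    else:
        cols = getattr(covariates, "columns", None)
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        cov_names = list(cols) if cols is not None else [f"c{i + 1}" for i in range(C.shape[1])]
    if covariate_names is not None:
        cov_names = list(covariate_names)
    if C.shape[0] != x.size:
        raise ValueError("covariate rows must match x/y length")

    keep = np.isfinite(x) & np.isfinite(y) & np.all(np.isfinite(C), axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("partial_correlation(%s, %s): dropped %d subject(s) with missing values", x_name, y_name, dropped)
    x, y, C = x[keep], y[keep], C[keep]
    n, k = x.size, C.shape[1]
    df = n - 2 - k
    if df < 1:
        raise ValueError(f"not enough observations (n={n}) for {k} covariates")

    design = np.column_stack([np.ones(n), C])
    beta_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ beta_x
    ry = y - design @ beta_y

    tol = 1e-12
    if rx.std() <= tol * max(1.0, np.abs(x).max()) or ry.std() <= tol * max(1.0, np.abs(y).max()):
        warnings.warn(
            f"partial_correlation({x_name}, {y_name}): a residual is (near-)constant; r set to 0",
            stacklevel=2,
        )
        return PartialCorrelationResult(x_name, y_name, cov_names, n, 0.0, 1.0)

    r = float(np.corrcoef(rx, ry)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return PartialCorrelationResult(x_name, y_name, cov_names, n, r, p)
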