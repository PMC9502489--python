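"""Construction of individual morphological similarity networks.

A subject's morphological brain network (MBN) has one node per atlas region.
The edge weight between two regions is a similarity derived from the
multivariate *energy distance* between the regions' vertex feature
distributions: regions whose gray-matter feature values are distributed alike
are strongly connected, regardless of their spatial location.

The pipeline is, per subject:

1. ``energy_distance`` for every region pair -> raw distance matrix ``e``;
2. per-subject min-max normalisation of the off-diagonal distances;
3. exponential conversion ``c = exp(-(e - e_min) / (e_max - e_min))``,

giving a symmetric R x R similarity matrix with zero diagonal, ``c = 1`` at
the subject's closest pair and ``c = exp(-1)`` at its farthest pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["SimilarityMatrix", "energy_distance", "distance_matrix", "similarity_matrix"]


def _as_vertex_matrix(values, name: str) -> np.ndarray:
    """Coerce a region's vertex features to a float (n_vertices, d) matrix."""
    arr = np.asarray(getattr(values, "values", values), dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ValueError(f"region {name!r}: need a non-empty (n_vertices, d) feature matrix")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"region {name!r}: non-finite feature values")
    return arr


def energy_distance(x, y) -> float:
    """Combined Euclidean (energy) distance between two vertex feature sets.

    With ``X = {x_1..x_n1}`` and ``Y = {y_1..y_n2}`` (rows of feature vectors),

        e(X, Y) = n1*n2/(n1+n2) * [ 2/(n1*n2) * sum_ij ||x_i - y_j||
                                    - 1/n1^2  * sum_ij ||x_i - x_j||
                                    - 1/n2^2  * sum_ij ||y_i - y_j|| ]

    using the Euclidean 2-norm. ``e >= 0`` with equality iff the two
    empirical distributions coincide, which is what makes it usable as a
    morphological dissimilarity between atlas regions.

    Parameters accept anything with a ``.values`` array or an array-like of
    shape ``(n,)`` or ``(n, d)``; both sets must share ``d``.
    """
    xm = _as_vertex_matrix(x, "X")
    ym = _as_vertex_matrix(y, "Y")
    if xm.shape[1] != ym.shape[1]:
        raise ValueError(
            f"feature dimensionality mismatch: X has d={xm.shape[1]}, Y has d={ym.shape[1]}"
        )
    n1, n2 = xm.shape[0], ym.shape[0]
    dxy = cdist(xm, ym).mean()
    dxx = cdist(xm, xm).mean()  # mean over n1^2 entries, zero diagonal included
    dyy = cdist(ym, ym).mean()
    e = n1 * n2 / (n1 + n2) * (2.0 * dxy - dxx - dyy)
    # the statistic is non-negative; round-off can leave a ~1e-16 negative
    return float(max(e, 0.0))


@dataclass
class SimilarityMatrix:
    """Per-subject morphological similarity network.

    Attributes
    ----------
    subject_id : str
    similarity : (R, R) float array, symmetric, zero diagonal, off-diagonal
        values in ``[exp(-1), 1]``.
    distance : (R, R) raw energy distances (zero diagonal).
    e_min, e_max : off-diagonal distance extremes used for normalisation.
    region_ids : region identifiers in matrix order.
    """

    subject_id: str
    similarity: np.ndarray
    distance: np.ndarray
    e_min: float
    e_max: float
    region_ids: list = field(default_factory=list)

    @property
    def n_regions(self) -> int:
        return self.similarity.shape[0]


def distance_matrix(regions) -> np.ndarray:
    """Raw pairwise energy-distance matrix over a sequence of regions."""
    mats = [_as_vertex_matrix(r, str(i)) for i, r in enumerate(regions)]
    d = {m.shape[1] for m in mats}
    if len(d) > 1:
        raise ValueError(f"regions disagree on feature dimensionality: {sorted(d)}")
    R = len(mats)
    e = np.zeros((R, R))
    for i in range(R):
        for j in range(i + 1, R):
            e[i, j] = e[j, i] = energy_distance(mats[i], mats[j])
    return e


def similarity_matrix(subject, subject_id: str | None = None) -> SimilarityMatrix:
    """Build a subject's similarity network from its region feature sets.

    ``subject`` is either a ``SubjectMorphology`` (regions in id order) or a
    plain sequence of vertex feature matrices. Normalisation is per subject:
    ``e_min``/``e_max`` are taken over this subject's R(R-1)/2 off-diagonal
    pairs. If every pair is equidistant the matrix is degenerate; all
    off-diagonal similarities are set to 1 and a warning is emitted.
    """
    regions = getattr(subject, "regions", subject)
    if subject_id is None:
        subject_id = str(getattr(subject, "subject_id", ""))
    region_ids = [getattr(r, "region_id", i) for i, r in enumerate(regions)]
    feats = [getattr(r, "values", r) for r in regions]
    R = len(feats)
    if R < 2:
        raise ValueError("need at least 2 regions to build a similarity matrix")

    e = distance_matrix(feats)
    if not np.all(np.isfinite(e)):
        raise ValueError(f"subject {subject_id!r}: non-finite energy distance")
    iu = np.triu_indices(R, k=1)
    e_min = float(e[iu].min())
    e_max = float(e[iu].max())

    if e_max == e_min:
        warnings.warn(
            f"subject {subject_id!r}: all region pairs equidistant; "
            "similarity matrix degenerates to all-ones off-diagonal",
            stacklevel=2,
        )
        c = np.ones((R, R))
    else:
        c = np.exp(-(e - e_min) / (e_max - e_min))
    np.fill_diagonal(c, 0.0)
    return SimilarityMatrix(
        subject_id=subject_id,
        similarity=c,
        distance=e,
        e_min=e_min,
        e_max=e_max,
        region_ids=list(region_ids),
    )


def write_similarity_tsv(sm: SimilarityMatrix, path) -> None:
    """Square TSV with region ids as header row/column; 17 significant digits."""
    import pandas as pd

    df = pd.DataFrame(sm.similarity, index=sm.region_ids, columns=sm.region_ids)
    df.to_csv(path, sep="\t", float_format="%.17g")


def write_similarity_npz(sm: SimilarityMatrix, path) -> None:
    """Binary alternative to the TSV format (NumPy ``.npz``), exactly lossless.

    Stores the similarity and raw-distance matrices, the normalisation
    extremes and the region ids; prefer TSV for interchange, this for bulk
    storage of large cohorts.
    """
    np.savez_compressed(
        path,
        similarity=sm.similarity,
        distance=sm.distance,
        e_min=sm.e_min,
        e_max=sm.e_max,
        region_ids=np.asarray(sm.region_ids),
        subject_id=np.asarray(sm.subject_id),
    )


def read_similarity_npz(path) -> SimilarityMatrix:
    with np.load(path, allow_pickle=False) as z:
        return SimilarityMatrix(
            subject_id=str(z["subject_id"]),
            similarity=z["similarity"],
            distance=z["distance"],
            e_min=float(z["e_min"]),
            e_max=float(z["e_max"]),
            region_ids=list(z["region_ids"].tolist()),
        )


def read_similarity_tsv(path, subject_id: str = "") -> SimilarityMatrix:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    c = df.to_numpy(dtype=float)
    if c.shape[0] != c.shape[1]:
        raise ValueError(f"{path}: similarity matrix is not square ({c.shape})")
    return SimilarityMatrix(
        subject_id=subject_id,
        similarity=c,
        distance=np.full_like(c, np.nan),
        e_min=float("nan"),
        e_max=float("nan"),
        region_ids=list(df.index),
    )
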