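"""Distance-based trimming of extreme cells (the high-dimensional method).

Within each cluster, every cell's Euclidean distances to its ``k`` nearest
within-cluster neighbours are computed in normalized gene-expression space.
The extremity statistic is the *minimum* of those k distances,
``min D_i = min_{j=1..k} D_{j,i}``: a large value means the cell sits in a
sparsely populated or peripheral region of its cluster. Cells with
``min D_i`` strictly above the per-cluster empirical ``(1 - alpha)``
quantile ``Q_{1-alpha}`` are flagged extreme, and trimming removes that
fraction ``alpha`` (equivalently keeps ``keep_frac = 1 - alpha``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .containers import ClusterAssignment, ExpressionMatrix

DEFAULT_K = 30  # neighbourhood size convention for the extremity statistic

CORE, EXTREME = "core", "extreme"


@dataclass
class NeighborDistances:
    """Per-cell within-cluster kNN distances and the min-distance statistic.

    ``distances[i]`` is sorted ascending and ``neighbor_ids[i]`` is aligned
    to it; ``min_dist[i]`` equals ``distances[i][0]``. Cells in singleton
    clusters carry an empty neighbour list and ``min_dist = +inf``.
    """

    k: int
    cell_ids: list[str]
    cluster_of: pd.Series
    neighbor_ids: list[list[str]]
    distances: list[np.ndarray]
    min_dist: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cluster": self.cluster_of.to_numpy(),
            "min_dist": self.min_dist,
        }, index=pd.Index(self.cell_ids, name="cell_id"))


@dataclass
class TrimResult:
    """Outcome of quantile trimming: flags plus per-cluster thresholds."""

    alpha: float
    thresholds: dict[str, float]
    flags: pd.Series  # cell_id -> "core" | "extreme"
    min_dist: pd.Series

    @property
    def keep_frac(self) -> float:
        return 1.0 - self.alpha

    @property
    def extreme_ids(self) -> list[str]:
        return list(self.flags.index[self.flags == EXTREME])

    @property
    def core_ids(self) -> list[str]:
        return list(self.flags.index[self.flags == CORE])

    def to_frame(self, clusters: ClusterAssignment | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"min_dist": self.min_dist, "flag": self.flags})
        df.index.name = "cell_id"
        if clusters is not None:
            df.insert(0, "cluster", [clusters.label_of(c) for c in df.index])
            df["threshold"] = [self.thresholds[cl] for cl in df["cluster"]]
        return df


def _knn_sorted(points: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact within-group kNN, self excluded: (distances, indices), sorted."""
    c = points.shape[0]
    if c <= 2000:
        dm = cdist(points, points)
        np.fill_diagonal(dm, np.inf)
        idx = np.argsort(dm, axis=1, kind="stable")[:, :k]
        dist = np.take_along_axis(dm, idx, axis=1)
    else:  # memory-friendly path for very large clusters
        from sklearn.neighbors import NearestNeighbors
        nn = NearestNeighbors(n_neighbors=k + 1).fit(points)
        dist, idx = nn.kneighbors(points)
        # drop self: it appears with distance 0; remove its own index if
        # present, else the first zero-distance duplicate
        keep_d, keep_i = [], []
        for i in range(c):
            row_i, row_d = list(idx[i]), list(dist[i])
            pos = row_i.index(i) if i in row_i else int(np.argmin(row_d))
            del row_i[pos], row_d[pos]
            keep_d.append(row_d[:k])
            keep_i.append(row_i[:k])
        dist, idx = np.asarray(keep_d), np.asarray(keep_i)
    return dist, idx


def compute_min_knn_distance(m: ExpressionMatrix, clusters: ClusterAssignment,
                             k: int = DEFAULT_K,
                             feature_set: list[str] | None = None) -> NeighborDistances:
    """Within-cluster kNN distances and ``min D_i`` for every cell.

    Distances are Euclidean over the selected feature rows (all genes when
    ``feature_set`` is None) of the normalized expression matrix. Clusters
    with ``c <= k`` cells use the effective neighbourhood ``c - 1``;
    singleton clusters get ``min_dist = +inf`` and a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if m.layer == "counts":
        raise ValueError("distances are computed on a normalized layer "
                         "(lognorm or clr), not raw counts")
    X = m.cells_matrix(feature_set)  # cells x features
    by_cluster = clusters.indices_by_cluster(m.cell_ids)

    n = m.n_cells
    min_dist = np.empty(n)
    neighbor_ids: list[list[str]] = [[] for _ in range(n)]
    distances: list[np.ndarray] = [np.empty(0) for _ in range(n)]
    labels = [clusters.label_of(c) for c in m.cell_ids]

    for cl, idx in by_cluster.items():
        c = idx.size
        if c == 1:
            warnings.warn(f"cluster {cl!r} is a singleton; min_dist set to +inf")
            min_dist[idx[0]] = np.inf
            continue
        eff_k = min(k, c - 1)
        dist, local = _knn_sorted(X[idx], eff_k)
        for row, i in enumerate(idx):
            distances[i] = dist[row]
            neighbor_ids[i] = [m.cell_ids[idx[j]] for j in local[row]]
            min_dist[i] = dist[row][0]

    return NeighborDistances(
        k=k, cell_ids=list(m.cell_ids),
        cluster_of=pd.Series(labels, index=m.cell_ids, name="cluster"),
        neighbor_ids=neighbor_ids, distances=distances, min_dist=min_dist)


def quantile_type7(values: np.ndarray, q: float) -> float:
    """Empirical quantile with linear interpolation (type-7 convention)."""
    return float(np.quantile(np.asarray(values, dtype=float), q, method="linear"))


def trim_cells(nd: NeighborDistances, clusters: ClusterAssignment,
               alpha: float) -> TrimResult:
    """Flag cells whose ``min D_i`` strictly exceeds ``Q_{1-alpha}``.

    The threshold is the per-cluster empirical ``(1 - alpha)`` quantile of
    the ``min D`` values (type-7 linear interpolation); ties at the
    threshold stay core. ``alpha = 0`` flags nothing. Singleton clusters
    (infinite sentinel) are always kept core.
    """
    if not (0 <= alpha < 1):
        raise ValueError(f"alpha must lie in [0, 1), got {alpha}")
    by_cluster = clusters.indices_by_cluster(nd.cell_ids)
    flags = np.array([CORE] * len(nd.cell_ids), dtype=object)
    thresholds: dict[str, float] = {}
    for cl, idx in by_cluster.items():
        vals = nd.min_dist[idx]
        if idx.size == 1 or not np.all(np.isfinite(vals)):
            if not np.all(np.isfinite(vals)):
                warnings.warn(f"cluster {cl!r} has non-finite min_dist "
                              "(singleton); kept core")
                thresholds[cl] = np.inf
                continue
        thr = quantile_type7(vals, 1.0 - alpha)
        thresholds[cl] = thr
        flags[idx[vals > thr]] = EXTREME
    index = pd.Index(nd.cell_ids, name="cell_id")
    return TrimResult(alpha=alpha, thresholds=thresholds,
                      flags=pd.Series(flags, index=index, name="flag"),
                      min_dist=pd.Series(nd.min_dist, index=index, name="min_dist"))


def trim_dist(m: ExpressionMatrix, clusters: ClusterAssignment,
              knn_k: int = DEFAULT_K, keep_frac: float = 0.9,
              feature_set: list[str] | None = None
              ) -> tuple[TrimResult, ExpressionMatrix]:
    """Convenience composition: kNN distances then trimming.

    ``keep_frac`` in (0, 1] is the fraction of cells retained per cluster
    (``alpha = 1 - keep_frac``). Returns the flags and the matrix
    restricted to core cells.
    """
    if not (0 < keep_frac <= 1):
        raise ValueError(f"keep_frac must lie in (0, 1], got {keep_frac}")
    nd = compute_min_knn_distance(m, clusters, k=knn_k, feature_set=feature_set)
    res = trim_cells(nd, clusters, alpha=1.0 - keep_frac)
    return res, m.subset_cells(res.core_ids)
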