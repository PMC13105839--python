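"""Hull-based trimming on a 2-D embedding (the embedding-level variant).

Each cluster's point cloud in the 2-D embedding (t-SNE/UMAP) is wrapped in
an alpha hull — a concave generalisation of the convex hull whose
tightness is set by ``hull_alpha``: large values give smooth, inclusive
boundaries converging to the convex hull, small values give tight,
irregular contours. Cells whose minimum Euclidean distance to their own
cluster's boundary falls strictly below the per-cluster
``outlier_quantile`` quantile of those distances are flagged as extreme
(near-border) cells.

Caveat: 2-D embeddings can shift individual cells away from where they sit
in the high-dimensional space, so the distance-based method of
:mod:`sctrim.knn_trim` is the recommended default; this variant is kept
for embedding-level workflows and visual diagnostics.

The alpha hull is realised as an alpha shape: Delaunay triangles whose
circumradius is at most ``hull_alpha`` are kept and their union's boundary
is the hull. Degenerate clusters (fewer than 3 distinct points, collinear
points, or an alpha too small to keep any triangle) fall back to their
convex hull with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError
from shapely.geometry import MultiPoint, Point, Polygon
from shapely.ops import unary_union

from .containers import ClusterAssignment, Embedding2D
from .knn_trim import CORE, EXTREME, quantile_type7


@dataclass
class AlphaHull:
    """Boundary of one cluster in the embedding.

    ``geometry`` is a shapely Polygon/MultiPolygon (or a degenerate
    LineString/Point fallback); ``boundary`` is the closed curve distances
    are measured to.
    """

    cluster: str
    hull_alpha: float
    geometry: object
    member_ids: list[str]
    fallback: bool = False

    @property
    def boundary(self):
        if self.geometry.geom_type in ("Polygon", "MultiPolygon"):
            return self.geometry.boundary
        return self.geometry  # degenerate: the segment/point itself

    @property
    def area(self) -> float:
        return float(self.geometry.area)

    @property
    def perimeter(self) -> float:
        return float(self.boundary.length)

    def boundary_coords(self) -> list[np.ndarray]:
        """Closed boundary ring(s) as (m, 2) arrays, for replotting."""
        b = self.boundary
        if b.geom_type == "Point":
            return [np.asarray(b.coords)]
        geoms = b.geoms if hasattr(b, "geoms") else [b]
        return [np.asarray(g.coords) for g in geoms]


@dataclass
class HullTrimResult:
    """Per-cell hull distances, per-cluster thresholds and flags."""

    outlier_quantile: float
    thresholds: dict[str, float]
    flags: pd.Series
    dist_to_hull: pd.Series
    hulls: list[AlphaHull]

    @property
    def extreme_ids(self) -> list[str]:
        return list(self.flags.index[self.flags == EXTREME])

    @property
    def core_ids(self) -> list[str]:
        return list(self.flags.index[self.flags == CORE])

    def to_frame(self, clusters: ClusterAssignment) -> pd.DataFrame:
        df = pd.DataFrame({"dist_to_hull": self.dist_to_hull, "flag": self.flags})
        df.index.name = "cell_id"
        df.insert(0, "cluster", [clusters.label_of(c) for c in df.index])
        df["threshold"] = [self.thresholds[cl] for cl in df["cluster"]]
        return df


def _circumradii(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    a = points[simplices[:, 0]]
    b = points[simplices[:, 1]]
    c = points[simplices[:, 2]]
    la = np.linalg.norm(b - c, axis=1)
    lb = np.linalg.norm(a - c, axis=1)
    lc = np.linalg.norm(a - b, axis=1)
    cross = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - \
            (b[:, 1] - a[:, 1]) * (c[:, 0] - a[:, 0])
    area = 0.5 * np.abs(cross)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = la * lb * lc / (4.0 * area)
    r[~np.isfinite(r)] = np.inf
    return r


def alpha_shape(points: np.ndarray, hull_alpha: float):
    """Alpha shape of a 2-D point set; convex-hull fallback when degenerate.

    Returns ``(geometry, fallback_flag)``.
    """
    if hull_alpha <= 0:
        raise ValueError("hull_alpha must be positive")
    pts = np.asarray(points, dtype=float)
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite embedding coordinates")
    unique = np.unique(pts, axis=0)
    if unique.shape[0] < 3:
        return MultiPoint([tuple(p) for p in pts]).convex_hull, True
    try:
        tri = Delaunay(unique)
    except QhullError:
        return MultiPoint([tuple(p) for p in pts]).convex_hull, True
    keep = _circumradii(unique, tri.simplices) <= hull_alpha
    if not keep.any():
        return MultiPoint([tuple(p) for p in pts]).convex_hull, True
    polys = [Polygon(unique[s]) for s in tri.simplices[keep]]
    geom = unary_union(polys)
    if geom.is_empty or geom.area == 0:
        return MultiPoint([tuple(p) for p in pts]).convex_hull, True
    return geom, False


def compute_alpha_hull(emb: Embedding2D, clusters: ClusterAssignment,
                       hull_alpha: float) -> list[AlphaHull]:
    """One alpha hull per cluster at the given concavity parameter."""
    by_cluster = clusters.indices_by_cluster(emb.cell_ids)
    hulls = []
    for cl, idx in by_cluster.items():
        geom, fb = alpha_shape(emb.coords[idx], hull_alpha)
        if fb:
            warnings.warn(f"cluster {cl!r}: degenerate or too-tight alpha shape; "
                          "using the convex hull instead")
        hulls.append(AlphaHull(cluster=cl, hull_alpha=hull_alpha, geometry=geom,
                               member_ids=[emb.cell_ids[i] for i in idx],
                               fallback=fb))
    return hulls


def distance_to_hull(emb: Embedding2D, hulls: list[AlphaHull]) -> pd.Series:
    """Minimum Euclidean distance from each cell to its cluster's boundary."""
    by_hull = {h.cluster: h for h in hulls}
    pos = {c: i for i, c in enumerate(emb.cell_ids)}
    dist = np.full(len(emb.cell_ids), np.nan)
    for h in hulls:
        boundary = by_hull[h.cluster].boundary
        for cid in h.member_ids:
            i = pos[cid]
            dist[i] = boundary.distance(Point(emb.coords[i]))
    return pd.Series(dist, index=pd.Index(emb.cell_ids, name="cell_id"),
                     name="dist_to_hull")


def trim_hull(emb: Embedding2D, clusters: ClusterAssignment,
              hull_alpha: float, outlier_quantile: float
              ) -> tuple[HullTrimResult, tuple[list[str], list[str]]]:
    """Flag cells strictly below the per-cluster hull-distance quantile.

    Returns the result object plus the ``(core_ids, extreme_ids)``
    partition; dropping the extreme cells mirrors ``remove.outliers``
    semantics.
    """
    if not (0 <= outlier_quantile <= 1):
        raise ValueError(f"outlier_quantile must lie in [0, 1], got {outlier_quantile}")
    hulls = compute_alpha_hull(emb, clusters, hull_alpha)
    dist = distance_to_hull(emb, hulls)
    by_cluster = clusters.indices_by_cluster(emb.cell_ids)
    flags = np.array([CORE] * len(emb.cell_ids), dtype=object)
    thresholds: dict[str, float] = {}
    for cl, idx in by_cluster.items():
        vals = dist.to_numpy()[idx]
        thr = quantile_type7(vals, outlier_quantile)
        thresholds[cl] = thr
        flags[idx[vals < thr]] = EXTREME
    res = HullTrimResult(
        outlier_quantile=outlier_quantile, thresholds=thresholds,
        flags=pd.Series(flags, index=pd.Index(emb.cell_ids, name="cell_id"),
                        name="flag"),
        dist_to_hull=dist, hulls=hulls)
    return res, (res.core_ids, res.extreme_ids)
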