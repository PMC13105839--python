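"""Synthetic data generators.

Two families:

* Multivariate-normal cell clouds with controlled covariance structure
  (dense equicorrelation, AR-1, block, identity), used to study whether
  cells that are extreme in the high-dimensional space stay in the border
  area of a 2-D embedding. Ground-truth extremity is the Mahalanobis
  distance to the generating distribution.
* Count-based multi-cluster scRNA-like datasets with planted border cells
  (variance-inflated expression noise that pushes cells to the cluster
  periphery without changing cluster identity) and planted marker genes —
  uniformly expressed ("robust") markers per cluster plus, optionally, one
  "fragile" marker expressed only in the border cells of one cluster.

Every generator is fully seeded and byte-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .containers import ClusterAssignment, Embedding2D, ExpressionMatrix

COV_KINDS = ("high", "ar1", "block", "identity")


# --------------------------------------------------------------------------
# Gaussian clouds
# --------------------------------------------------------------------------

@dataclass
class SimScenario:
    """A seeded multivariate-normal cloud specification.

    ``cov`` picks the covariance family: ``high`` (dense equicorrelation,
    default pairwise correlation 0.9 — the 3-D high-covariance setting),
    ``ar1`` (corr(i, j) = rho^|i-j|), ``block`` (``n_blocks`` equal blocks
    with within-block correlation rho) or ``identity``. Unit variances
    throughout; the structure, not the scale, is what matters here.
    """

    n_cells: int = 1000
    dim: int = 3
    cov: str = "high"
    rho: float | None = None
    n_blocks: int = 4
    seed: int = 0

    def covariance(self) -> np.ndarray:
        if self.cov not in COV_KINDS:
            raise ValueError(f"cov must be one of {COV_KINDS}")
        d = self.dim
        if self.cov == "identity":
            return np.eye(d)
        if self.cov == "high":
            rho = 0.9 if self.rho is None else self.rho
            return np.full((d, d), rho) + (1 - rho) * np.eye(d)
        if self.cov == "ar1":
            rho = 0.5 if self.rho is None else self.rho
            idx = np.arange(d)
            return rho ** np.abs(idx[:, None] - idx[None, :])
        rho = 0.6 if self.rho is None else self.rho
        sigma = np.eye(d)
        sizes = np.full(self.n_blocks, d // self.n_blocks)
        sizes[: d % self.n_blocks] += 1
        start = 0
        for size in sizes:
            sigma[start:start + size, start:start + size] = \
                np.full((size, size), rho) + (1 - rho) * np.eye(size)
            start += size
        return sigma


@dataclass
class GaussianCloud:
    """Sampled points with ground-truth Mahalanobis extremity."""

    points: np.ndarray          # n_cells x dim
    mahalanobis: np.ndarray     # distance to the generating mean/covariance
    scenario: SimScenario

    @property
    def extremity_rank(self) -> np.ndarray:
        """Rank 0 = most extreme cell."""
        return np.argsort(np.argsort(-self.mahalanobis))


def gen_gaussian_cloud(s: SimScenario) -> GaussianCloud:
    """Seeded multivariate-normal draw plus per-cell Mahalanobis distance."""
    sigma = s.covariance()
    try:
        chol = cho_factor(sigma, lower=True)
    except np.linalg.LinAlgError as e:  # pragma: no cover - guarded families
        raise ValueError("covariance matrix is not positive definite") from e
    rng = np.random.default_rng(s.seed)
    pts = rng.multivariate_normal(np.zeros(s.dim), sigma, size=s.n_cells,
                                  method="cholesky")
    maha = np.sqrt(np.einsum("ij,ij->i", pts, cho_solve(chol, pts.T).T))
    return GaussianCloud(points=pts, mahalanobis=maha, scenario=s)


def locational_shift_score(mahalanobis: np.ndarray, emb: Embedding2D,
                           q: float = 0.05) -> float:
    """Concordance of high-dimensional extremes with the 2-D border area.

    The score is the fraction of the top-``q`` Mahalanobis-extreme cells
    that land in the top-``2q`` of 2-D distance-to-centroid. 1 means every
    high-dimensional extreme sits in the embedding's border area; under an
    embedding independent of extremity the expected score is about ``2q``.
    """
    if not (0 < q <= 0.5):
        raise ValueError(f"q must lie in (0, 0.5], got {q}")
    maha = np.asarray(mahalanobis, dtype=float)
    n = maha.size
    if n != len(emb.cell_ids):
        raise ValueError("mahalanobis values and embedding differ in cell count")
    center_dist = np.linalg.norm(emb.coords - emb.coords.mean(axis=0), axis=1)
    k = max(1, int(round(q * n)))
    k2 = max(1, int(round(2 * q * n)))
    top_hd = np.argsort(-maha, kind="stable")[:k]
    top_2d = set(np.argsort(-center_dist, kind="stable")[:k2])
    return sum(1 for i in top_hd if i in top_2d) / k


# --------------------------------------------------------------------------
# planted scRNA-like datasets
# --------------------------------------------------------------------------

@dataclass
class PlantedParams:
    """Knobs of the planted-outlier / planted-marker count generator.

    Border cells get their per-gene log-normal expression noise variance
    inflated by ``inflation`` (standard deviation times sqrt(inflation)),
    which pushes them to the sparse periphery of their cluster in
    normalized expression space while keeping the cluster's mean profile.
    """

    n_clusters: int = 3
    cells_per_cluster: int = 100
    n_genes: int = 150
    markers_per_cluster: int = 10
    marker_log2fc: float = 2.0       # planted fold change 2**2 = 4x
    border_frac: float = 0.1
    inflation: float = 4.0           # variance inflation of border-cell noise
    core_log_sd: float = 0.5         # log-normal expression noise of core cells
    base_mean_log_mu: float = 1.5    # lognormal prior of per-gene base means
    base_mean_log_sd: float = 0.6
    nb_dispersion: float = 10.0      # NB size; var = mu + mu^2/size
    libsize_log_sd: float = 0.1
    fragile_cluster: int | None = None  # plant a border-only marker here
    fragile_mean: float = 25.0
    fragile_background: float = 0.0  # the gene is silent outside border cells
    seed: int = 0


@dataclass
class PlantedDataset:
    """Counts plus full ground truth of the planting design."""

    counts: ExpressionMatrix
    clusters: ClusterAssignment
    outlier_flags: pd.Series            # cell_id -> bool (planted border cell)
    marker_design: dict[str, list[str]]  # cluster -> uniformly planted markers
    fragile: tuple[str, str] | None      # (cluster, gene) of the border-only marker
    params: PlantedParams


def gen_planted_dataset(params: PlantedParams | None = None, **overrides) -> PlantedDataset:
    """Negative-binomial counts with planted clusters, border cells, markers."""
    p = params or PlantedParams()
    if overrides:
        from dataclasses import replace
        p = replace(p, **overrides)
    if p.n_clusters < 2:
        raise ValueError("need at least 2 clusters")
    if not (0 <= p.border_frac < 0.5):
        raise ValueError("border_frac must lie in [0, 0.5)")
    if p.inflation < 1:
        raise ValueError("inflation must be >= 1")
    if p.n_genes < p.n_clusters * p.markers_per_cluster + 1:
        raise ValueError("not enough genes for the requested marker design")
    rng = np.random.default_rng(p.seed)

    n_cells = p.n_clusters * p.cells_per_cluster
    gene_ids = [f"g{g:04d}" for g in range(p.n_genes)]
    cell_ids = [f"c{i:04d}" for i in range(n_cells)]
    cluster_names = [f"cl{c}" for c in range(p.n_clusters)]

    base = rng.lognormal(p.base_mean_log_mu, p.base_mean_log_sd, size=p.n_genes)
    marker_design: dict[str, list[str]] = {}
    mean_by_cluster = np.tile(base, (p.n_clusters, 1))
    g = 0
    for c, cl in enumerate(cluster_names):
        planted = list(range(g, g + p.markers_per_cluster))
        g += p.markers_per_cluster
        mean_by_cluster[c, planted] *= 2.0 ** p.marker_log2fc
        marker_design[cl] = [gene_ids[j] for j in planted]

    fragile = None
    fragile_gene_idx = None
    if p.fragile_cluster is not None:
        fragile_gene_idx = p.n_genes - 1
        fragile = (cluster_names[p.fragile_cluster], gene_ids[fragile_gene_idx])
        mean_by_cluster[:, fragile_gene_idx] = p.fragile_background

    labels = np.repeat(np.arange(p.n_clusters), p.cells_per_cluster)
    n_border = int(round(p.border_frac * p.cells_per_cluster))
    is_border = np.zeros(n_cells, dtype=bool)
    for c in range(p.n_clusters):
        members = np.flatnonzero(labels == c)
        is_border[rng.choice(members, size=n_border, replace=False)] = True

    log_sd = np.where(is_border, p.core_log_sd * np.sqrt(p.inflation), p.core_log_sd)
    libsize = rng.lognormal(0.0, p.libsize_log_sd, size=n_cells)

    counts = np.empty((p.n_genes, n_cells), dtype=np.int64)
    theta = p.nb_dispersion
    for i in range(n_cells):
        mu = mean_by_cluster[labels[i]].copy()
        if fragile_gene_idx is not None and is_border[i] and \
                labels[i] == p.fragile_cluster:
            mu[fragile_gene_idx] = p.fragile_mean
        mu = mu * np.exp(rng.normal(0.0, log_sd[i], size=p.n_genes)) * libsize[i]
        counts[:, i] = rng.negative_binomial(theta, theta / (theta + mu))

    em = ExpressionMatrix(counts, gene_ids, cell_ids, layer="counts")
    clusters = ClusterAssignment.from_arrays(
        cell_ids, [cluster_names[c] for c in labels])
    flags = pd.Series(is_border, index=pd.Index(cell_ids, name="cell_id"),
                      name="planted_border")
    return PlantedDataset(counts=em, clusters=clusters, outlier_flags=flags,
                          marker_design=marker_design, fragile=fragile, params=p)
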