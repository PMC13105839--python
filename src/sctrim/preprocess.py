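"""Standard scRNA-seq preprocessing: normalisation, HVG selection, and a
reproducible filter → normalise → HVG → scale → PCA → cluster → embed
pipeline that produces the inputs the trimming core operates on.

The two normalisations follow the conventional definitions:

* LogNormalize: ``x -> ln(1 + s * x / total(cell))`` with scale factor
  ``s`` (default 10 000).
* CLR (centred log-ratio): within each cell,
  ``x -> ln(1 + x / exp(mean_g ln(1 + x_g)))`` where the mean runs over
  all genes of that cell (zeros included).

Clustering is graph-based community detection (Leiden on a kNN graph of
the PCA space) and the 2-D embedding is t-SNE; both are delegated to
established implementations and fully seeded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .containers import ClusterAssignment, Embedding2D, ExpressionMatrix


# --------------------------------------------------------------------------
# normalisations
# --------------------------------------------------------------------------

def log_normalize(m: ExpressionMatrix, scale_factor: float = 10_000.0) -> ExpressionMatrix:
    """Library-size normalisation to ``scale_factor`` followed by log1p."""
    if m.layer != "counts":
        raise ValueError(f"log_normalize expects a counts layer, got {m.layer!r}")
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    totals = m.cell_totals()
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        bad = [m.cell_ids[i] for i in zero[:10]]
        raise ValueError(f"cells with zero total counts cannot be normalised: {bad}")
    if sp.issparse(m.values):
        out = m.values.tocsc().astype(float, copy=True)
        scale = scale_factor / totals
        out = out @ sp.diags(scale)
        out.data = np.log1p(out.data)
    else:
        out = np.log1p(m.values * (scale_factor / totals)[None, :])
    return m.with_values(out, "lognorm")


def clr_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Centred log-ratio normalisation within each cell (across genes)."""
    if m.layer != "counts":
        raise ValueError(f"clr_normalize expects a counts layer, got {m.layer!r}")
    d = m.n_genes
    if sp.issparse(m.values):
        csc = m.values.tocsc().astype(float)
        log1p_sums = np.zeros(m.n_cells)
        for j in range(m.n_cells):
            col = csc.data[csc.indptr[j]:csc.indptr[j + 1]]
            log1p_sums[j] = np.log1p(col).sum()
        geo = np.exp(log1p_sums / d)  # zeros contribute ln(1+0)=0 to the mean
        out = csc.copy()
        for j in range(m.n_cells):
            lo, hi = out.indptr[j], out.indptr[j + 1]
            out.data[lo:hi] = np.log1p(out.data[lo:hi] / geo[j])
    else:
        geo = np.exp(np.log1p(m.values).mean(axis=0))
        out = np.log1p(m.values / geo[None, :])
    return m.with_values(out, "clr")


# --------------------------------------------------------------------------
# highly variable genes
# --------------------------------------------------------------------------

def _gene_moments(values) -> tuple[np.ndarray, np.ndarray]:
    if sp.issparse(values):
        n = values.shape[1]
        mean = np.asarray(values.mean(axis=1)).ravel()
        sq = values.multiply(values).mean(axis=1)
        var = (np.asarray(sq).ravel() - mean ** 2) * n / max(n - 1, 1)
    else:
        mean = values.mean(axis=1)
        var = values.var(axis=1, ddof=1) if values.shape[1] > 1 else np.zeros(values.shape[0])
    return mean, var


def standardized_variance(m: ExpressionMatrix) -> np.ndarray:
    """Per-gene variance-stabilised standardized variance on raw counts.

    Fits a lowess trend of log10 variance against log10 mean, standardises
    each count by the trend-expected standard deviation (clipping the
    standardized values at sqrt(n)), and returns the variance of the
    clipped standardized values — the usual "vst" ranking statistic.
    """
    if m.layer != "counts":
        raise ValueError("HVG selection runs on the counts layer")
    n = m.n_cells
    mean, var = _gene_moments(m.values)
    out = np.zeros(m.n_genes)
    fit_mask = (mean > 0) & (var > 0)
    if fit_mask.sum() == 0:
        return out
    if fit_mask.sum() >= 5:
        from statsmodels.nonparametric.smoothers_lowess import lowess
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitted = lowess(np.log10(var[fit_mask]), np.log10(mean[fit_mask]),
                            frac=0.3, return_sorted=False)
        expected_var = 10 ** fitted
    else:
        # too few informative genes for a trend: Poisson-like expectation
        expected_var = mean[fit_mask]
    bad = ~np.isfinite(expected_var) | (expected_var <= 0)
    if bad.any():
        expected_var = np.where(bad, var[fit_mask], expected_var)
    expected_sd = np.sqrt(expected_var)

    dense = m.to_dense() if n * m.n_genes <= 5_000_000 else None
    clip = np.sqrt(n)
    rows = np.flatnonzero(fit_mask)
    for pos, i in enumerate(rows):
        row = (dense[i] if dense is not None
               else np.asarray(m.values[i].todense()).ravel())
        z = (row - mean[i]) / expected_sd[pos]
        np.clip(z, -clip, clip, out=z)
        out[i] = z.var(ddof=1) if n > 1 else 0.0
    return out


def select_hvg(m: ExpressionMatrix, n_features: int) -> list[str]:
    """Top ``min(n_features, d)`` gene ids by standardized variance.

    Deterministic: ties and the tail are broken by original gene order.
    """
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    stat = standardized_variance(m)
    order = np.argsort(-stat, kind="stable")
    k = min(int(n_features), m.n_genes)
    return [m.gene_ids[i] for i in order[:k]]


# --------------------------------------------------------------------------
# scaling / PCA / clustering / embedding
# --------------------------------------------------------------------------

def zscore_genes(m: ExpressionMatrix, clip: float = 10.0) -> np.ndarray:
    """Per-gene z-scaling of a normalized layer; returns dense genes x cells."""
    x = m.to_dense()
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True) if m.n_cells > 1 else np.ones_like(mu)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    return np.clip(z, -clip, clip)


def run_pca(cells_by_features: np.ndarray, n_pcs: int, seed: int = 0) -> np.ndarray:
    from sklearn.decomposition import PCA
    n_pcs = min(n_pcs, min(cells_by_features.shape) - 1)
    n_pcs = max(n_pcs, 1)
    return PCA(n_components=n_pcs, svd_solver="full",
               random_state=seed).fit_transform(cells_by_features)


def leiden_cluster(coords: np.ndarray, k: int = 15, resolution: float = 1.0,
                   seed: int = 0) -> np.ndarray:
    """Leiden community detection on an undirected kNN graph of ``coords``."""
    import igraph
    import leidenalg
    from sklearn.neighbors import kneighbors_graph

    n = coords.shape[0]
    k = min(k, n - 1)
    adj = kneighbors_graph(coords, n_neighbors=k, mode="connectivity")
    adj = adj.maximum(adj.T).tocoo()
    edges = [(int(i), int(j)) for i, j in zip(adj.row, adj.col) if i < j]
    g = igraph.Graph(n=n, edges=edges)
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=seed, n_iterations=2)
    return np.asarray(part.membership, dtype=int)


def tsne_embed(coords: np.ndarray, seed: int = 0, perplexity: float = 30.0) -> np.ndarray:
    from sklearn.manifold import TSNE
    n = coords.shape[0]
    perplexity = min(perplexity, (n - 1) / 3.5)
    return TSNE(n_components=2, perplexity=perplexity, init="pca",
                random_state=seed).fit_transform(coords)


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Settings of the standard workflow.

    ``min_features``/``max_features`` bound the number of detected genes
    per cell (None disables a bound); ``norm`` is ``lognorm`` or ``clr``;
    ``n_hvg`` preselects variable genes; ``n_pcs`` is the PCA dimension
    used for clustering; everything stochastic consumes ``seed``.
    """

    min_features: int | None = 200
    max_features: int | None = 2500
    norm: str = "lognorm"
    scale_factor: float = 10_000.0
    n_hvg: int = 2000
    n_pcs: int = 10
    graph_k: int = 15
    resolution: float = 1.0
    perplexity: float = 30.0
    seed: int = 0


@dataclass
class PipelineResult:
    """Everything downstream stages need, aligned on the filtered cells."""

    counts: ExpressionMatrix
    normalized: ExpressionMatrix
    hvgs: list[str]
    pca: np.ndarray
    clusters: ClusterAssignment
    embedding: Embedding2D

    def __iter__(self):
        # the (normalized, clusters, embedding) contract
        return iter((self.normalized, self.clusters, self.embedding))


def run_standard_pipeline(m: ExpressionMatrix, cfg: PipelineConfig | None = None) -> PipelineResult:
    """Filter → normalise → HVG → scale → PCA → Leiden → t-SNE."""
    cfg = cfg or PipelineConfig()
    if m.layer != "counts":
        raise ValueError("pipeline starts from a counts layer")

    if sp.issparse(m.values):
        detected = np.asarray((m.values != 0).sum(axis=0)).ravel()
    else:
        detected = (m.values != 0).sum(axis=0)
    keep = np.ones(m.n_cells, dtype=bool)
    if cfg.min_features is not None:
        keep &= detected >= cfg.min_features
    if cfg.max_features is not None:
        keep &= detected <= cfg.max_features
    if keep.sum() < 2:
        raise ValueError(
            f"only {int(keep.sum())} cells survive the feature-count filter "
            f"[{cfg.min_features}, {cfg.max_features}]")
    counts = m if keep.all() else m.subset_cells([m.cell_ids[i] for i in np.flatnonzero(keep)])

    if cfg.norm == "lognorm":
        norm = log_normalize(counts, cfg.scale_factor)
    elif cfg.norm == "clr":
        norm = clr_normalize(counts)
    else:
        raise ValueError(f"unknown normalisation {cfg.norm!r}")

    hvgs = select_hvg(counts, cfg.n_hvg)
    scaled = zscore_genes(norm.subset_genes(hvgs))
    pca = run_pca(scaled.T, cfg.n_pcs, seed=cfg.seed)
    membership = leiden_cluster(pca, k=cfg.graph_k, resolution=cfg.resolution,
                                seed=cfg.seed)
    clusters = ClusterAssignment.from_arrays(norm.cell_ids, membership)
    coords = tsne_embed(pca, seed=cfg.seed, perplexity=cfg.perplexity)
    emb = Embedding2D(coords, list(norm.cell_ids), method="tsne")
    return PipelineResult(counts, norm, hvgs, pca, clusters, emb)
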