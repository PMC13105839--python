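# Methods

This note documents the models, conventions and numerical choices behind
`sctrim`, and what the synthetic-data generators do and do not emulate.

## Extreme-cell detection

### Distance-based trimming (`sctrim.knn_trim`)

For every cell *i*, the *k* nearest within-cluster Euclidean distances
*D*<sub>*j*,*i*</sub> are computed in normalized expression space and the
extremity statistic is min *D*<sub>*i*</sub> = min<sub>*j*</sub>
*D*<sub>*j*,*i*</sub>. Cells with min *D*<sub>*i*</sub> strictly above
the per-cluster empirical (1−α) quantile *Q*<sub>1−α</sub> of these
values are flagged extreme.

Conventions and edge cases:

- **Neighbourhood size** defaults to *k* = 30. The statistic is the
  *minimum* over the k distances, so k acts as an upper bound on how much
  local context is aggregated; within a cluster of *c* ≤ *k* cells the
  effective neighbourhood is *c* − 1 (all other members). Singleton
  clusters cannot be scored; they receive a `+inf` sentinel, are always
  kept core, and trigger a warning.
- **Quantile convention**: type-7 linear interpolation (the default of
  most statistical environments), and the flagging rule is strict
  (`min_dist > threshold`), so ties at the threshold stay core and
  α = 0 flags nothing. Flagged sets are nested in α because the
  threshold is non-increasing while the values are fixed.
- **Feature space**: distances are computed on the normalized
  (un-scaled) expression values, by default restricted to the HVG subset
  used by the surrounding pipeline (`feature_set` argument); passing no
  feature set uses all genes. z-scored input is deliberately not the
  default: scaling reweights genes per-dataset and makes thresholds
  harder to compare across variants.
- **Search strategy**: exact brute-force pairwise distances within each
  cluster (clusters are small relative to the dataset); a
  memory-friendly kNN index is used automatically above 2000 cells per
  cluster. Exactness is tested against a brute-force oracle.

### Hull-based trimming (`sctrim.hull_trim`)

The 2-D variant wraps each cluster's embedding coordinates in an alpha
hull and flags cells whose minimum distance to their own cluster's
boundary is strictly below the per-cluster `outlier_quantile` quantile
(type-7 again, mirroring the distance-based rule). The alpha hull is
realised as an alpha shape: Delaunay triangles with circumradius at most
`hull_alpha` are kept and the union's boundary is the hull, so large
`hull_alpha` converges to the convex hull and small values produce
tighter, possibly disconnected contours. Degenerate clusters (fewer than
3 distinct points, collinear points, or an alpha so small that no
triangle survives) fall back to their convex hull with a warning rather
than failing. Boundary distances are exact shapely point-to-curve
distances (no discretisation); cells on the boundary have distance 0 and
are flagged whenever the threshold is positive.

This variant is retained for embedding-level workflows, but dimension
reduction can relocate individual cells relative to their
high-dimensional position (see the simulation below), so the
distance-based method is the recommended default.

## Standard workflow (`sctrim.preprocess`)

- **LogNormalize**: x → ln(1 + s·x/total(cell)), scale factor s = 10 000
  by default (the common library-size convention).
- **CLR**: within each cell, x → ln(1 + x / exp(mean<sub>g</sub> ln(1 +
  x<sub>g</sub>))) with the mean over *all* genes of that cell (zeros
  included). Computing CLR within cells keeps it symmetric to
  LogNormalize's per-cell scaling; a per-gene margin would answer a
  different question.
- **HVG selection**: variance-stabilised ranking. A lowess trend of
  log10 variance against log10 mean (frac 0.3) predicts each gene's
  expected standard deviation; counts are standardised by it, clipped at
  √n, and genes are ranked by the variance of the clipped values. With
  fewer than five informative genes the trend degenerates and a
  Poisson-like expectation (variance = mean) is used instead.
- **Cell filters** default to 200–2500 detected features per cell
  (tutorial convention; both bounds optional).
- **Clustering and embedding** are delegated: PCA (full SVD,
  deterministic), an undirected kNN graph (k = 15), Leiden community
  detection (RB-configuration, resolution 1.0, seeded), and t-SNE
  (PCA initialisation, seeded, perplexity capped at (n−1)/3.5 for small
  inputs). With a fixed seed the whole pipeline is bitwise repeatable.

## Marker detection (`sctrim.markers`)

One-vs-rest per cluster. Genes are prefiltered on detection fraction
(max(pct_in, pct_out) ≥ 0.1) and log2 fold-change (|log2fc| ≥ 0.25,
computed as log2((mean(expm1 x_in)+1)/(mean(expm1 x_out)+1)) — the
pseudocount-on-de-logged-means convention). Tested genes get a two-sided
Wilcoxon rank-sum p-value:

- both groups ≤ 10 cells: exact permutation enumeration over all
  C(n, n₁) assignments of the rank-sum statistic (midranks, so ties are
  handled exactly);
- otherwise: tie-corrected normal approximation *without* continuity
  correction. The continuity-corrected variant is slightly conservative;
  the uncorrected textbook z keeps the null rejection rate centred on
  the nominal level, which the test suite verifies (5% ± 2% over 200
  null datasets).

Adjustment is Bonferroni over the genes tested within each cluster, and
rows must pass p_adj ≤ 0.05; `only_positive` (default) keeps
over-expressed markers. Some toolkits Bonferroni-correct over all genes
in the object instead; that stricter universe can be emulated by scaling
p_adj_max.

## Set comparison and breakdown (`sctrim.setcompare`)

S1/S2/S3 partition the union of S_full and S_trim, so
|S1|+|S2|+|S3| = m holds exactly and P₁+P₂+P₃ = 100 exactly at the
rational level; each reported percentage is the correctly rounded
100·k/m (float sums agree with 100 to ~1 ulp). An empty union (m = 0)
yields all percentages 0 with a `no_markers` annotation. Swapping the
full and trimmed inputs swaps P₁ and P₃ bit-exactly.

`trim_effect` runs the full-vs-trimmed comparison under two analysis
variants (e.g. LogNormalize vs CLR, or two HVG budgets) on *fixed*
cluster labels — trimming never re-clusters, so clusters are matched by
label identity — and emits a variant-blocked long table for the heatmap.

`breakdown_profile` recomputes markers at each trimming level (default
0, 10, 20, 30, 40%) against the fixed level-0 baseline and reports
retention = 100·|S_full ∩ S_trim(α)|/|S_full| per cluster. Note the
denominator differs from the P₂ denominator m: retention asks how much of
the *original* marker set survives. Retention is not mathematically
monotone in α (marker sets are re-estimated per level); only the planted
fixtures gate a monotone trend.

## Synthetic data (`sctrim.simulate`)

### Gaussian clouds

`SimScenario` draws n cells from a zero-mean multivariate normal with
unit variances and one of four correlation structures: dense
equicorrelation (default ρ = 0.9 — the "high covariance" 3-D setting),
AR-1 (ρ = 0.5), block (4 blocks, within-block ρ = 0.6), or identity.
Ground-truth extremity is the Mahalanobis distance to the generating
distribution. `locational_shift_score` then measures whether the top-q
Mahalanobis extremes land in the top-2q of 2-D distance-to-centroid in an
embedding: 1 means perfect border concordance, ≈ 2q is the independence
level. For the 3-D high-covariance cloud under t-SNE the score is far
above independence (≈ 0.4–0.5 at q = 0.05) but well below 1, i.e. even
here the 2-D border area is an imperfect proxy for high-dimensional
extremity — the reason the kNN method is the default.

### Planted datasets

`gen_planted_dataset` builds negative-binomial counts (dispersion
θ = 10, so var = μ + μ²/10) for (default) 3 clusters × 100 cells × 150
genes. Per-gene base means are drawn log-normal(1.5, 0.6) (≈ 4.5 counts
median, a realistic moderately expressed panel); each cluster gets 10
markers at a planted 4× fold change; per-cell, per-gene biological noise
is log-normal with σ = 0.5 for core cells, and border cells (10% per
cluster) have that noise *variance* inflated ×4 (σ ×2), which pushes
them to the sparse periphery of their cluster without moving the cluster
mean. Library sizes vary log-normally (σ = 0.1). Optionally one
"fragile" marker is planted that is expressed (mean 25) *only* in the
border cells of one cluster and is exactly silent elsewhere — the
cleanest realisation of a marker that exists only because of border
cells. The noise scales were fixed once when the generator was designed:
with sampling noise much larger (low base means), the planted ×4
variance inflation would be undetectable by any method, which would test
the generator rather than the trimming rule.

What the generator does **not** emulate: ambient RNA, doublets, batch
effects, gene–gene correlation beyond the planted cluster structure, and
continuous trajectories. Passing tests therefore demonstrate the
correctness and discriminating power of the trimming and comparison
machinery under a clean planted-truth model, not end-to-end performance
on real tissue data, where border cells arise from messier mechanisms.

## Problem sizes and determinism

All simulations are sized for interactive runs: 300-cell planted
datasets, 1000-cell clouds, 200-replicate calibration loops; every
stochastic step consumes an explicit seed and all generators are
byte-deterministic given (params, seed). The acceptance script derives
per-analysis seeds from a single `--seed` argument by fixed offsets.

## Known limitations

- Trimming small clusters reduces power; clusters at or below the
  neighbourhood size fall back to c−1 neighbours and singletons are
  never trimmed.
- The alpha-shape fallback to the convex hull (degenerate geometry)
  changes the boundary semantics for those clusters; a warning is
  always emitted.
- The Wilcoxon stand-in mirrors the common default marker test but not
  alternatives (MAST, logistic models, pseudobulk); comparisons between
  marker universes produced by different testing frameworks should hold
  the test fixed.
- Marker-set comparisons assume cluster labels are fixed before
  trimming; re-clustering the trimmed data would require set matching
  across label spaces, which is deliberately out of scope.
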