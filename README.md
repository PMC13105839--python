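# sctrim

Robustness analysis of scRNA-seq marker selection by trimming extreme
cells from clusters.

## The problem

Unsupervised clustering of single-cell RNA-seq data assigns every cell to
a cluster, but some cells sit in sparsely populated border regions of
their cluster: biological extremes, transition states, or simply cells
that landed in the wrong cluster. Downstream results — above all the
per-cluster marker genes that define cell types — can hinge on exactly
these cells. `sctrim` follows the logic of trimmed estimators from robust
statistics: identify the extreme cells of each cluster, re-run the
analysis without them, and quantify how much the result changed. Running
the analysis twice (full vs trimmed) is far cheaper than bootstrap-style
resampling and directly points at the clusters whose markers are fragile.

The toolkit is aimed at analysts who already have a clustered count
matrix (e.g. from a standard Seurat/Scanpy-style workflow) and want to
know which of their marker sets survive the removal of border cells, and
at methodologists comparing analysis variants (normalisation, feature
selection, number of PCs) under a common robustness yardstick.

## The method

**Extreme-cell detection (high-dimensional, recommended).** Within each
cluster, compute for every cell *i* the Euclidean distances
*D*<sub>*j*,*i*</sub> to its *k* nearest within-cluster neighbours in
normalized gene-expression space (default *k* = 30) and summarise them by

&nbsp;&nbsp;&nbsp;&nbsp;min *D*<sub>*i*</sub> = min<sub>*j*=1..*k*</sub> *D*<sub>*j*,*i*</sub>.

A large min *D*<sub>*i*</sub> means the cell lies in a sparsely populated
peripheral region. Cells with min *D*<sub>*i*</sub> > *Q*<sub>1−α</sub>,
the empirical (1−α) quantile of the min *D* values of their cluster, are
flagged *extreme*; trimming removes that fraction α per cluster
(equivalently keeps `keep_frac` = 1−α, default 0.9).

**Extreme-cell detection (2-D variant).** Alternatively, wrap each
cluster's points in a 2-D embedding (t-SNE/UMAP) in an alpha hull whose
concavity is set by `hull_alpha`, and flag cells whose minimum distance
to their own cluster's boundary falls below the per-cluster
`outlier_quantile` quantile. Because dimension reduction can relocate
individual cells relative to the high-dimensional geometry, the
high-dimensional kNN method is the default recommendation.

**Robustness statistics.** For each cluster, with marker sets
*S*<sub>full</sub> (complete data) and *S*<sub>trim</sub> (trimmed data):

- *S*<sub>1</sub> = *S*<sub>full</sub> \ *S*<sub>trim</sub>,
  *S*<sub>2</sub> = *S*<sub>full</sub> ∩ *S*<sub>trim</sub>,
  *S*<sub>3</sub> = *S*<sub>trim</sub> \ *S*<sub>full</sub>;
- *P*<sub>*i*</sub> = 100·|*S*<sub>*i*</sub>|/*m* with
  *m* = |*S*<sub>full</sub> ∪ *S*<sub>trim</sub>|.

High *P*<sub>2</sub> marks a robust cluster; high *P*<sub>1</sub> means
the full-data markers relied on border cells; high *P*<sub>3</sub> means
trimming changed the selection altogether. A *breakdown profile* extends
this across trimming levels (default 0–40%), reporting per cluster the
percentage of the original markers still recovered at each level.

The package also ships a self-contained standard workflow (10x MTX input,
LogNormalize/CLR, HVG selection, PCA, Leiden clustering, t-SNE), a
one-vs-rest Wilcoxon marker finder, heatmap renderers for the comparison
and breakdown tables, and seeded synthetic-data generators (Gaussian
clouds with controlled covariance; negative-binomial datasets with
planted border cells and planted robust/fragile markers).

## Worked example

```python
import sctrim as st

ds = st.gen_planted_dataset(st.PlantedParams(seed=1, fragile_cluster=0))
norm = st.log_normalize(ds.counts)

res, trimmed = st.trim_dist(norm, ds.clusters, knn_k=15, keep_frac=0.9)
print("flagged extreme:", len(res.extreme_ids), "of", norm.n_cells, "cells")

full = st.find_all_markers(norm, ds.clusters)
trim = st.find_all_markers(trimmed, ds.clusters.subset(trimmed.cell_ids))
cmp = st.compare_marker_sets(full, trim)
print(cmp.table[["cluster", "n_full", "n_trim", "p1", "p2", "p3"]]
      .round(1).to_string(index=False))

prof = st.breakdown_profile(norm, ds.clusters,
                            levels=(0.0, 0.1, 0.2, 0.3, 0.4),
                            trim=st.TrimConfig(knn_k=15))
print(prof.retention.round(1).to_string())
```

Output:

```
flagged extreme: 30 of 300 cells
cluster  n_full  n_trim  p1    p2  p3
    cl0      11      10 9.1  90.9 0.0
    cl1      10      10 0.0 100.0 0.0
    cl2      10      10 0.0 100.0 0.0
           0.0    0.1    0.2    0.3    0.4
cluster
cl0      100.0   90.9   90.9   90.9   90.9
cl1      100.0  100.0  100.0  100.0  100.0
cl2      100.0  100.0  100.0  100.0  100.0
```

The generator planted 10% border cells per cluster and, in cluster `cl0`,
one "fragile" marker expressed only in those border cells. Trimming 10%
of cells flags 30 cells; clusters `cl1`/`cl2` keep every marker
(*P*<sub>2</sub> = 100), while `cl0` loses exactly the border-driven gene
(*P*<sub>1</sub> = 9.1, one of eleven markers) — and the breakdown
profile shows that loss occurring at the first trimming level and staying
flat, the signature of a single fragile marker.

The same steps are available from the shell:

```sh
sctrim simulate --scenario planted --seed 1 --out sim/
sctrim trim-knn --input sim/ --labels sim/labels.tsv --k 15 --keep-frac 0.9 --out trim/
sctrim markers  --input sim/ --labels sim/labels.tsv --out markers.tsv
sctrim breakdown --input sim/ --labels sim/labels.tsv --k 15 --out breakdown/
```

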