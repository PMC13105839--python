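"""Robustness statistics for marker-set comparisons.

Given the marker set ``S_full`` from the complete data and ``S_trim``
from the trimmed data, the per-cluster decomposition is

* ``S1 = S_full \\ S_trim`` — markers lost by trimming,
* ``S2 = S_full ∩ S_trim`` — markers shared by both analyses,
* ``S3 = S_trim \\ S_full`` — markers gained by trimming,

with percentages ``P_i = 100 |S_i| / m`` over the union size
``m = |S_full ∪ S_trim|``. Large ``P2`` marks a robust cluster; large
``P1`` means the full-data markers relied on border cells; large ``P3``
means trimming changed the selection altogether.

The breakdown profile tracks, per cluster, the percentage of the original
(untrimmed) markers still recovered when trimming at increasing levels —
the trimmed-statistics notion of locating where a result destabilises.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ClusterAssignment, ExpressionMatrix
from .knn_trim import DEFAULT_K, trim_dist
from .markers import find_all_markers, marker_sets

COMPARISON_COLUMNS = ["cluster", "n_full", "n_trim", "s1", "s2", "s3", "m",
                      "p1", "p2", "p3", "no_markers"]


def _percentages(a: int, b: int, c: int) -> tuple[float, float, float]:
    """Percentages of (a, b, c) over their sum.

    The identity P1 + P2 + P3 = 100 holds exactly at the rational level
    (the cardinalities partition the union); each float is the correctly
    rounded ``100 k / m``, so swapping a and c swaps the percentages
    bit-exactly.
    """
    m = a + b + c
    if m == 0:
        return 0.0, 0.0, 0.0
    return 100.0 * a / m, 100.0 * b / m, 100.0 * c / m


@dataclass
class SetComparison:
    """Per-cluster S1/S2/S3 decomposition of full vs trimmed marker sets."""

    table: pd.DataFrame
    sets: dict[str, dict[str, set[str]]]  # cluster -> {"s1": .., "s2": .., "s3": ..}

    def per_cluster(self, cluster: str) -> pd.Series:
        return self.table.set_index("cluster").loc[cluster]

    def heatmap_table(self, variant: str | None = None) -> pd.DataFrame:
        """Long-format table (cluster x category x percentage) for heatmaps."""
        rows = []
        for _, r in self.table.iterrows():
            for cat, p, n in (("S1", r.p1, r.s1), ("S2", r.p2, r.s2),
                              ("S3", r.p3, r.s3)):
                rows.append({"cluster": r.cluster, "category": cat,
                             "percentage": p, "count": n,
                             "n_full": r.n_full, "n_trim": r.n_trim,
                             **({"variant": variant} if variant else {})})
        return pd.DataFrame(rows)


def _as_sets(markers) -> dict[str, set[str]]:
    if isinstance(markers, pd.DataFrame):
        return marker_sets(markers)
    return {str(k): set(v) for k, v in dict(markers).items()}


def compare_marker_sets(full, trimmed) -> SetComparison:
    """S1/S2/S3 cardinalities and percentages per cluster.

    ``full`` and ``trimmed`` are marker tables (or cluster -> gene-set
    mappings). Clusters present in only one input are compared against the
    empty set with a warning. A cluster with an empty union is annotated
    ``no_markers`` and gets all percentages 0.
    """
    sf, st = _as_sets(full), _as_sets(trimmed)
    only = set(sf) ^ set(st)
    if only:
        warnings.warn(f"clusters present in only one marker table: {sorted(only)}; "
                      "compared against the empty set")
    rows, sets = [], {}
    for cl in sorted(set(sf) | set(st)):
        s_full = sf.get(cl, set())
        s_trim = st.get(cl, set())
        s1, s2, s3 = s_full - s_trim, s_full & s_trim, s_trim - s_full
        m = len(s1) + len(s2) + len(s3)
        p1, p2, p3 = _percentages(len(s1), len(s2), len(s3))
        rows.append((cl, len(s_full), len(s_trim), len(s1), len(s2), len(s3),
                     m, p1, p2, p3, m == 0))
        sets[cl] = {"s1": s1, "s2": s2, "s3": s3}
    return SetComparison(pd.DataFrame(rows, columns=COMPARISON_COLUMNS), sets)


# --------------------------------------------------------------------------
# configs for the orchestrated comparisons
# --------------------------------------------------------------------------

@dataclass
class TrimConfig:
    """How cells are trimmed: neighbourhood size and kept fraction."""

    knn_k: int = DEFAULT_K
    keep_frac: float = 0.9
    feature_set: list[str] | None = None

    @property
    def alpha(self) -> float:
        return 1.0 - self.keep_frac


@dataclass
class MarkerConfig:
    """Marker-detection filter settings."""

    min_pct: float = 0.1
    log2fc_min: float = 0.25
    p_adj_max: float = 0.05
    only_positive: bool = True

    def kwargs(self) -> dict:
        return {"min_pct": self.min_pct, "log2fc_min": self.log2fc_min,
                "p_adj_max": self.p_adj_max, "only_positive": self.only_positive}


@dataclass
class VariantConfig:
    """One analysis variant: a normalisation plus an HVG budget.

    ``n_hvg = None`` keeps all genes as the distance feature space.
    """

    name: str
    norm: str = "lognorm"
    n_hvg: int | None = None
    scale_factor: float = 10_000.0


def _run_variant(counts: ExpressionMatrix, clusters: ClusterAssignment,
                 variant: VariantConfig, trim: TrimConfig,
                 marker: MarkerConfig) -> SetComparison:
    from .preprocess import clr_normalize, log_normalize, select_hvg

    if variant.norm == "lognorm":
        norm = log_normalize(counts, variant.scale_factor)
    elif variant.norm == "clr":
        norm = clr_normalize(counts)
    else:
        raise ValueError(f"unknown normalisation {variant.norm!r}")
    feature_set = trim.feature_set
    if feature_set is None and variant.n_hvg is not None:
        feature_set = select_hvg(counts, variant.n_hvg)
    full_markers = find_all_markers(norm, clusters, **marker.kwargs())
    res, trimmed = trim_dist(norm, clusters, knn_k=trim.knn_k,
                             keep_frac=trim.keep_frac, feature_set=feature_set)
    trim_markers = find_all_markers(trimmed, clusters.subset(trimmed.cell_ids),
                                    **marker.kwargs())
    return compare_marker_sets(full_markers, trim_markers)


@dataclass
class TrimEffectResult:
    """Paired full-vs-trimmed comparisons under two analysis variants."""

    comparisons: dict[str, SetComparison]
    heatmap: pd.DataFrame  # variant-blocked long table (Fig-style layout)


def trim_effect(counts: ExpressionMatrix, clusters: ClusterAssignment,
                variant_a: VariantConfig, variant_b: VariantConfig,
                trim: TrimConfig | None = None,
                marker: MarkerConfig | None = None) -> TrimEffectResult:
    """Quantify marker-set changes after trimming under two variants.

    Runs full and trimmed marker detection under each variant (e.g. two
    normalisations, or two HVG budgets) on the *fixed* cluster labels and
    returns both comparisons plus a single variant-blocked heatmap table
    with S1/S2/S3 percentages 0-100 and the full/trimmed marker totals.
    """
    trim = trim or TrimConfig()
    marker = marker or MarkerConfig()
    comparisons, blocks = {}, []
    for variant in (variant_a, variant_b):
        cmp = _run_variant(counts, clusters, variant, trim, marker)
        comparisons[variant.name] = cmp
        blocks.append(cmp.heatmap_table(variant=variant.name))
    return TrimEffectResult(comparisons, pd.concat(blocks, ignore_index=True))


@dataclass
class BreakdownProfile:
    """Marker retention (% of the untrimmed set) across trimming levels."""

    levels: list[float]
    baseline_counts: dict[str, int]
    retention: pd.DataFrame  # clusters x levels, percentages (NaN when baseline empty)

    def heatmap_table(self) -> pd.DataFrame:
        long = self.retention.reset_index(names="cluster").melt(
            id_vars="cluster", var_name="level", value_name="retention")
        long["baseline"] = long["cluster"].map(self.baseline_counts)
        return long

    def row_labels(self) -> list[str]:
        return [f"{cl} ({self.baseline_counts[cl]})" for cl in self.retention.index]


def breakdown_profile(norm: ExpressionMatrix, clusters: ClusterAssignment,
                      levels=(0.0, 0.1, 0.2, 0.3, 0.4),
                      trim: TrimConfig | None = None,
                      marker: MarkerConfig | None = None) -> BreakdownProfile:
    """Recompute markers at each trimming level against the level-0 baseline.

    ``retention(level) = 100 |S_full ∩ S_trim(level)| / |S_full|`` per
    cluster; clusters with an empty baseline get NaN. Levels must be
    ascending, start at 0 and stay below 1.
    """
    levels = [float(l) for l in levels]
    if not levels or levels[0] != 0.0 or sorted(levels) != levels or levels[-1] >= 1:
        raise ValueError("levels must be ascending, contain 0 and stay in [0, 1)")
    trim = trim or TrimConfig()
    marker = marker or MarkerConfig()
    baseline = marker_sets(find_all_markers(norm, clusters, **marker.kwargs()))
    names = clusters.subset(norm.cell_ids).cluster_names()
    baseline_counts = {cl: len(baseline.get(cl, set())) for cl in names}
    ret = pd.DataFrame(index=pd.Index(names, name="cluster"),
                       columns=levels, dtype=float)
    for level in levels:
        if level == 0.0:
            current = baseline
        else:
            _, trimmed = trim_dist(norm, clusters, knn_k=trim.knn_k,
                                   keep_frac=1.0 - level,
                                   feature_set=trim.feature_set)
            current = marker_sets(find_all_markers(
                trimmed, clusters.subset(trimmed.cell_ids), **marker.kwargs()))
        for cl in names:
            base = baseline.get(cl, set())
            if not base:
                ret.loc[cl, level] = np.nan
            else:
                ret.loc[cl, level] = 100.0 * len(base & current.get(cl, set())) / len(base)
    return BreakdownProfile(levels, baseline_counts, ret)
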