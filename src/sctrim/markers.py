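"""One-vs-rest marker-gene detection.

A self-contained stand-in for the usual per-cluster marker finder: for
every cluster, each gene is tested against all remaining cells with a
two-sided Wilcoxon rank-sum test (tie-corrected normal approximation;
exact permutation enumeration when both groups have at most 10 cells),
after prefiltering on detection fraction and log2 fold-change. P-values
are Bonferroni-adjusted over the genes tested per cluster.

The log2 fold-change follows the pseudocount-on-de-logged-means
convention: ``log2((mean(expm1(x_in)) + 1) / (mean(expm1(x_out)) + 1))``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

MARKER_COLUMNS = ["cluster", "gene", "log2fc", "pct_in", "pct_out", "p", "p_adj"]


@lru_cache(maxsize=32)
def _combo_matrix(n: int, n1: int) -> np.ndarray:
    return np.array(list(combinations(range(n), n1)), dtype=np.int32)


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p for the rank-sum statistic.

    Enumerates all C(n, n1) group assignments and measures how often the
    rank sum deviates from its permutation mean at least as much as
    observed; ties are handled exactly through midranks.
    """
    n1, n = len(x), len(x) + len(y)
    ranks = rankdata(np.concatenate([x, y]))
    w_obs = ranks[:n1].sum()
    mu = ranks.sum() * n1 / n
    combos = _combo_matrix(n, n1)
    w_null = ranks[combos].sum(axis=1)
    return float(np.mean(np.abs(w_null - mu) >= np.abs(w_obs - mu) - 1e-9))


def rank_sum_p(x, y, exact: bool | None = None) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    ``exact=None`` picks exact enumeration when both groups have at most
    10 observations, otherwise the tie-corrected normal approximation
    (no continuity correction).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if exact is None:
        exact = len(x) <= 10 and len(y) <= 10
    if exact:
        return _exact_rank_sum_p(x, y)
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0  # all values tied: no evidence either way
    _, p = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                        use_continuity=False)
    return float(p)


def find_all_markers(m, clusters, min_pct: float = 0.1,
                     log2fc_min: float = 0.25, p_adj_max: float = 0.05,
                     only_positive: bool = True) -> pd.DataFrame:
    """Per-cluster marker table from a normalized expression matrix.

    Returns a DataFrame with columns ``cluster, gene, log2fc, pct_in,
    pct_out, p, p_adj`` containing, for every cluster, the genes that pass
    the detection (``min_pct``), effect-size (``log2fc_min``) and adjusted
    significance (``p_adj_max``) filters; ``only_positive`` keeps
    over-expressed markers only. Rows are ordered by cluster then
    ascending p then descending log2fc.
    """
    if m.layer == "counts":
        raise ValueError("marker detection runs on a normalized layer")
    names = clusters.cluster_names()
    if len(names) < 2:
        raise ValueError("marker detection needs at least 2 clusters "
                         "(no reference group otherwise)")
    X = m.to_dense()  # genes x cells
    by_cluster = clusters.indices_by_cluster(m.cell_ids)
    n = m.n_cells
    rows = []
    for cl in names:
        idx_in = by_cluster[cl]
        mask_in = np.zeros(n, dtype=bool)
        mask_in[idx_in] = True
        x_in, x_out = X[:, mask_in], X[:, ~mask_in]
        pct_in = (x_in > 0).mean(axis=1)
        pct_out = (x_out > 0).mean(axis=1)
        mean_in = np.expm1(x_in).mean(axis=1)
        mean_out = np.expm1(x_out).mean(axis=1)
        log2fc = np.log2((mean_in + 1.0) / (mean_out + 1.0))
        tested = (np.maximum(pct_in, pct_out) >= min_pct) & \
                 (np.abs(log2fc) >= log2fc_min)
        g_tested = int(tested.sum())
        for gi in np.flatnonzero(tested):
            p = rank_sum_p(x_in[gi], x_out[gi])
            p_adj = min(1.0, p * g_tested)
            if p_adj > p_adj_max:
                continue
            if only_positive and log2fc[gi] <= 0:
                continue
            rows.append((cl, m.gene_ids[gi], float(log2fc[gi]),
                         float(pct_in[gi]), float(pct_out[gi]), p, p_adj))
    table = pd.DataFrame(rows, columns=MARKER_COLUMNS)
    if len(table):
        table = table.sort_values(["cluster", "p", "log2fc"],
                                  ascending=[True, True, False],
                                  kind="stable").reset_index(drop=True)
    return table


def marker_sets(table: pd.DataFrame) -> dict[str, set[str]]:
    """Per-cluster marker gene-id sets from a marker table."""
    if len(table) == 0:
        return {}
    return {cl: set(sub["gene"]) for cl, sub in table.groupby("cluster")}
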