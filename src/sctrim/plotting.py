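"""Rendering of the comparison heatmaps and trimming overlays.

All functions return a matplotlib Figure and never call ``show``; pass a
path to save directly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
from matplotlib.colors import LinearSegmentedColormap  # noqa: E402

from .containers import ClusterAssignment, Embedding2D  # noqa: E402

_WHITE_RED = LinearSegmentedColormap.from_list("white_red", ["white", "red"])
_RED_BLUE = LinearSegmentedColormap.from_list("red_blue", ["red", "white", "blue"])


def _save(fig, path):
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
    return fig


def trim_effect_heatmap(heatmap: pd.DataFrame, path=None):
    """Cluster x (variant-blocked S1/S2/S3) percentage heatmap.

    Expects the long table from ``trim_effect`` (columns cluster,
    category, percentage, count, n_full, n_trim, variant). Cell totals per
    variant are shown in parentheses next to the cluster label.
    """
    variants = list(dict.fromkeys(heatmap.get("variant", pd.Series(["run"]))))
    clusters = list(dict.fromkeys(heatmap["cluster"]))
    cats = ["S1", "S2", "S3"]
    cols = [(v, c) for v in variants for c in cats]
    mat = np.full((len(clusters), len(cols)), np.nan)
    for _, r in heatmap.iterrows():
        v = r.get("variant", "run")
        mat[clusters.index(r["cluster"]), cols.index((v, r["category"]))] = r["percentage"]

    fig, ax = plt.subplots(figsize=(1.2 * len(cols) + 3, 0.5 * len(clusters) + 2))
    im = ax.imshow(mat, cmap=_WHITE_RED, vmin=0, vmax=100, aspect="auto")
    ax.set_xticks(range(len(cols)),
                  [f"{c}\n{v}" for v, c in cols], fontsize=8)
    labels = []
    for cl in clusters:
        sub = heatmap[heatmap["cluster"] == cl]
        totals = " / ".join(f"({int(s.iloc[0].n_full)}, {int(s.iloc[0].n_trim)})"
                            for _, s in sub.groupby("variant", sort=False))
        labels.append(f"{cl} {totals}")
    ax.set_yticks(range(len(clusters)), labels, fontsize=8)
    for i in range(len(clusters)):
        for j in range(len(cols)):
            if np.isfinite(mat[i, j]):
                ax.text(j, i, f"{mat[i, j]:.1f}", ha="center", va="center",
                        fontsize=7)
    fig.colorbar(im, ax=ax, label="% of marker union")
    ax.set_title("Marker-set change after trimming")
    return _save(fig, path)


def breakdown_heatmap(profile, path=None):
    """Cluster x trimming-level retention heatmap (100 = fully retained)."""
    ret = profile.retention
    fig, ax = plt.subplots(figsize=(1.0 * len(ret.columns) + 3,
                                    0.5 * len(ret) + 2))
    im = ax.imshow(ret.to_numpy(dtype=float), cmap=_RED_BLUE, vmin=0, vmax=100,
                   aspect="auto")
    ax.set_xticks(range(len(ret.columns)),
                  [f"{100 * l:.0f}%" for l in ret.columns])
    ax.set_yticks(range(len(ret)), profile.row_labels(), fontsize=8)
    for i in range(ret.shape[0]):
        for j in range(ret.shape[1]):
            v = ret.iloc[i, j]
            if np.isfinite(v):
                ax.text(j, i, f"{v:.0f}", ha="center", va="center", fontsize=7)
    fig.colorbar(im, ax=ax, label="% of original markers retained")
    ax.set_xlabel("trimming level")
    ax.set_title("Breakdown profile of marker retention")
    return _save(fig, path)


def embedding_overlay(emb: Embedding2D, clusters: ClusterAssignment,
                      flags: pd.Series | None = None, hulls=None, path=None):
    """2-D embedding coloured by cluster; extreme cells outlined in black."""
    fig, ax = plt.subplots(figsize=(6, 5))
    names = clusters.cluster_names()
    cmap = plt.get_cmap("tab20")
    pos = {c: i for i, c in enumerate(emb.cell_ids)}
    for ci, cl in enumerate(names):
        idx = [pos[c] for c in clusters.members(cl) if c in pos]
        ax.scatter(emb.coords[idx, 0], emb.coords[idx, 1], s=12,
                   color=cmap(ci % 20), label=cl, linewidths=0)
    if flags is not None:
        ext = [pos[c] for c, f in flags.items() if f == "extreme" and c in pos]
        ax.scatter(emb.coords[ext, 0], emb.coords[ext, 1], s=26,
                   facecolors="none", edgecolors="black", linewidths=0.8,
                   label="extreme")
    if hulls is not None:
        for h in hulls:
            for ring in h.boundary_coords():
                ax.plot(ring[:, 0], ring[:, 1], color="grey", lw=0.8)
    ax.legend(fontsize=7, markerscale=1.5, loc="best")
    ax.set_xlabel(f"{emb.method} 1")
    ax.set_ylabel(f"{emb.method} 2")
    return _save(fig, path)
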