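"""Core in-memory containers.

The toolkit works on a genes x cells expression matrix (the matrix ``X``
with ``d`` gene rows and ``n`` cell columns that every scRNA-seq workflow
starts from), a per-cell cluster assignment, and an optional 2-D embedding
used only for visualisation and for the hull-based trimming variant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

LAYER_TAGS = ("counts", "lognorm", "clr")


def _as_2d(values):
    if sp.issparse(values):
        return values.tocsc()
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expression values must be 2-D, got shape {arr.shape}")
    return arr


@dataclass
class ExpressionMatrix:
    """Genes x cells expression matrix with identifiers.

    Parameters
    ----------
    values
        ``(d, n)`` dense array or scipy sparse matrix; genes are rows,
        cells are columns (CellRanger convention).
    gene_ids, cell_ids
        Unique identifiers for the ``d`` rows and ``n`` columns.
    layer
        One of ``counts`` (non-negative integers), ``lognorm`` or ``clr``.
    """

    values: object
    gene_ids: list[str]
    cell_ids: list[str]
    layer: str = "counts"

    def __post_init__(self):
        self.values = _as_2d(self.values)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        d, n = self.values.shape
        if d < 1 or n < 1:
            raise ValueError("matrix must have at least one gene and one cell")
        if len(self.gene_ids) != d:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {d} rows")
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} columns")
        if len(set(self.cell_ids)) != n:
            raise ValueError("duplicate cell ids")
        if len(set(self.gene_ids)) != d:
            raise ValueError("duplicate gene ids (disambiguate before building)")
        if self.layer not in LAYER_TAGS:
            raise ValueError(f"layer must be one of {LAYER_TAGS}, got {self.layer!r}")
        data = self.values.data if sp.issparse(self.values) else self.values
        if not np.all(np.isfinite(data)):
            raise ValueError("expression values must be finite")
        if self.layer == "counts":
            if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
                raise ValueError("counts layer must hold non-negative integers")

    # -- basic geometry ------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return np.asarray(self.values, dtype=float)

    # -- indexing ------------------------------------------------------
    def gene_index(self, gene_ids: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in lookup]
        if missing:
            raise KeyError(f"gene ids not in matrix: {missing[:5]}")
        return np.array([lookup[g] for g in gene_ids], dtype=int)

    def cell_index(self, cell_ids: Sequence[str]) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.cell_ids)}
        missing = [c for c in cell_ids if c not in lookup]
        if missing:
            raise KeyError(f"cell ids not in matrix: {missing[:5]}")
        return np.array([lookup[c] for c in cell_ids], dtype=int)

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_index(gene_ids)
        return ExpressionMatrix(self.values[idx, :], [self.gene_ids[i] for i in idx],
                                list(self.cell_ids), self.layer)

    def subset_cells(self, cell_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = self.cell_index(cell_ids)
        return ExpressionMatrix(self.values[:, idx], list(self.gene_ids),
                                [self.cell_ids[i] for i in idx], self.layer)

    def with_values(self, values, layer: str) -> "ExpressionMatrix":
        return ExpressionMatrix(values, list(self.gene_ids), list(self.cell_ids), layer)

    def cell_totals(self) -> np.ndarray:
        """Per-cell total counts (column sums)."""
        if sp.issparse(self.values):
            return np.asarray(self.values.sum(axis=0)).ravel()
        return self.values.sum(axis=0)

    def cells_matrix(self, gene_ids: Sequence[str] | None = None) -> np.ndarray:
        """Dense cells x features matrix (transposed view for distance work)."""
        m = self if gene_ids is None else self.subset_genes(gene_ids)
        return m.to_dense().T


@dataclass
class ClusterAssignment:
    """Cell -> cluster label map; every cell has exactly one label."""

    labels: dict[str, str]

    def __post_init__(self):
        self.labels = {str(c): str(l) for c, l in self.labels.items()}
        if not self.labels:
            raise ValueError("empty cluster assignment")

    @classmethod
    def from_series(cls, s: pd.Series) -> "ClusterAssignment":
        return cls(dict(zip(s.index.astype(str), s.astype(str))))

    @classmethod
    def from_arrays(cls, cell_ids: Sequence[str], labels: Sequence) -> "ClusterAssignment":
        if len(cell_ids) != len(labels):
            raise ValueError("cell_ids and labels differ in length")
        return cls(dict(zip(map(str, cell_ids), map(str, labels))))

    def label_of(self, cell_id: str) -> str:
        try:
            return self.labels[cell_id]
        except KeyError:
            raise KeyError(f"cell {cell_id!r} has no cluster label") from None

    def cluster_names(self) -> list[str]:
        return sorted(set(self.labels.values()))

    def members(self, cluster: str) -> list[str]:
        return [c for c, l in self.labels.items() if l == cluster]

    def indices_by_cluster(self, cell_ids: Sequence[str]) -> dict[str, np.ndarray]:
        """Per-cluster positional indices into the given cell order."""
        out: dict[str, list[int]] = {}
        for i, c in enumerate(cell_ids):
            out.setdefault(self.label_of(str(c)), []).append(i)
        return {k: np.array(v, dtype=int) for k, v in sorted(out.items())}

    def subset(self, cell_ids: Sequence[str]) -> "ClusterAssignment":
        return ClusterAssignment({c: self.label_of(str(c)) for c in cell_ids})

    def to_series(self, cell_ids: Sequence[str] | None = None) -> pd.Series:
        if cell_ids is None:
            cell_ids = list(self.labels)
        return pd.Series({c: self.label_of(str(c)) for c in cell_ids}, name="cluster")


@dataclass
class Embedding2D:
    """n x 2 coordinates aligned to ``cell_ids`` (t-SNE/UMAP style)."""

    coords: np.ndarray
    cell_ids: list[str]
    method: str = "tsne"

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError(f"embedding must be n x 2, got {self.coords.shape}")
        if self.coords.shape[0] != len(self.cell_ids):
            raise ValueError("coordinate rows do not match cell ids")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("embedding coordinates must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.coords, index=self.cell_ids, columns=["x", "y"])
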