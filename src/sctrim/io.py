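"""Reading and writing standard single-cell file formats.

Supports the 10x Genomics triplet layout (``matrix.mtx`` MatrixMarket
coordinate file plus ``barcodes.tsv`` and ``features.tsv``/``genes.tsv``,
optionally gzipped), flat label TSVs (``cell_id<TAB>cluster``) and 2-D
embedding TSVs (``cell_id<TAB>x<TAB>y``).
"""

from __future__ import annotations

import gzip
import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import ClusterAssignment, Embedding2D, ExpressionMatrix

_MTX_NAMES = ("matrix.mtx", "matrix.mtx.gz")
_BARCODE_NAMES = ("barcodes.tsv", "barcodes.tsv.gz")
_FEATURE_NAMES = ("features.tsv", "features.tsv.gz", "genes.tsv", "genes.tsv.gz")


def _find(dir_path: Path, candidates) -> Path:
    for name in candidates:
        p = dir_path / name
        if p.exists():
            return p
    raise FileNotFoundError(
        f"none of {candidates} found in {dir_path}")


def _read_tsv_column(path: Path, column: int = 0) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    out = []
    with opener(path, "rt") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            out.append(line.split("\t")[column])
    return out


def make_unique(names: list[str]) -> list[str]:
    """Disambiguate duplicate names by suffixing ``.1``, ``.2``, ..."""
    seen: dict[str, int] = {}
    out = []
    for name in names:
        if name in seen:
            seen[name] += 1
            out.append(f"{name}.{seen[name]}")
        else:
            seen[name] = 0
            out.append(name)
    return out


def read_10x_mtx(dir_path) -> ExpressionMatrix:
    """Read a 10x triplet directory into a counts :class:`ExpressionMatrix`.

    Genes are rows and cells are columns; the 1-based MatrixMarket indices
    become 0-based internally. Duplicate gene symbols are made unique by
    suffixing. Raises ``FileNotFoundError`` naming the missing file, and a
    ``ValueError`` when the header dimensions disagree with the TSV lengths.
    """
    dir_path = Path(dir_path)
    if not dir_path.is_dir():
        raise FileNotFoundError(f"no such directory: {dir_path}")
    mtx_path = _find(dir_path, _MTX_NAMES)
    barcodes = _read_tsv_column(_find(dir_path, _BARCODE_NAMES))
    feature_path = _find(dir_path, _FEATURE_NAMES)
    # features.tsv carries (id, symbol, type); genes.tsv carries (id, symbol).
    # The human-readable symbol (2nd column if present) names the gene.
    ids = _read_tsv_column(feature_path, 0)
    try:
        symbols = _read_tsv_column(feature_path, 1)
    except IndexError:
        symbols = ids
    with (gzip.open(mtx_path, "rb") if mtx_path.suffix == ".gz" else open(mtx_path, "rb")) as fh:
        mat = scipy.io.mmread(fh)
    mat = sp.csc_matrix(mat)
    d, n = mat.shape
    if d != len(symbols):
        raise ValueError(
            f"matrix has {d} gene rows but feature file lists {len(symbols)}")
    if n != len(barcodes):
        raise ValueError(
            f"matrix has {n} cell columns but barcode file lists {len(barcodes)}")
    return ExpressionMatrix(mat, make_unique(symbols), make_unique(barcodes),
                            layer="counts")


def write_10x_mtx(m: ExpressionMatrix, dir_path, gzip_files: bool = False) -> None:
    """Write the matrix as a 10x triplet (MTX + barcodes + genes TSVs)."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    suffix = ".gz" if gzip_files else ""
    values = sp.coo_matrix(m.values)
    mtx_path = dir_path / f"matrix.mtx{suffix}"
    if gzip_files:
        with gzip.open(mtx_path, "wb") as fh:
            scipy.io.mmwrite(fh, values)
    else:
        scipy.io.mmwrite(os.fspath(mtx_path), values)
    opener = gzip.open if gzip_files else open
    with opener(dir_path / f"barcodes.tsv{suffix}", "wt") as fh:
        fh.write("\n".join(m.cell_ids) + "\n")
    with opener(dir_path / f"genes.tsv{suffix}", "wt") as fh:
        fh.write("\n".join(f"{g}\t{g}" for g in m.gene_ids) + "\n")


def read_labels_tsv(path) -> ClusterAssignment:
    """Read ``cell_id<TAB>cluster`` (header optional, detected)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"label file {path} needs two columns")
    if df.iloc[0, 0].lower() in {"cell", "cell_id", "barcode"}:
        df = df.iloc[1:]
    return ClusterAssignment.from_arrays(df.iloc[:, 0], df.iloc[:, 1])


def write_labels_tsv(clusters: ClusterAssignment, path) -> None:
    with open(path, "w") as fh:
        fh.write("cell_id\tcluster\n")
        for c, l in clusters.labels.items():
            fh.write(f"{c}\t{l}\n")


def read_embedding_tsv(path, method: str = "tsne") -> Embedding2D:
    """Read ``cell_id<TAB>x<TAB>y`` (header optional, detected)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 3:
        raise ValueError(f"embedding file {path} needs three columns")
    if df.iloc[0, 0].lower() in {"cell", "cell_id", "barcode"}:
        df = df.iloc[1:]
    coords = df.iloc[:, 1:3].astype(float).to_numpy()
    return Embedding2D(coords, list(df.iloc[:, 0]), method=method)


def write_embedding_tsv(emb: Embedding2D, path) -> None:
    with open(path, "w") as fh:
        fh.write("cell_id\tx\ty\n")
        for cid, (x, y) in zip(emb.cell_ids, emb.coords):
            fh.write(f"{cid}\t{x:.10g}\t{y:.10g}\n")
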