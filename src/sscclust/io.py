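"""Readers and writers for the formats the pipeline touches.

Two expression formats are supported:

* ``mtx_triplet`` — 10x-style triplet: ``matrix.mtx`` (Matrix Market
  coordinate, genes x cells, 1-based) plus ``genes.tsv`` and
  ``barcodes.tsv`` sidecars in the same directory.
* ``dense_tsv`` — tab/comma-separated table, first row = cell ids,
  first column = gene ids.

Labels travel as a two-column TSV (cell_id, cluster).
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datamodel import ExpressionMatrix, FormatError, LabelVector, ValidationError

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_labels",
    "write_labels",
]

_SIDE_GENES = ("genes.tsv", "features.tsv")
_SIDE_CELLS = ("barcodes.tsv",)


def _find_sidecar(folder: Path, names: tuple[str, ...]) -> Path:
    for name in names:
        p = folder / name
        if p.exists():
            return p
    raise FormatError(f"missing sidecar file ({' or '.join(names)}) in {folder}")


def _read_ids(path: Path) -> list[str]:
    # 10x genes.tsv may carry two columns (id, symbol); the first is the id
    ids = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return ids


def read_matrix(path: str | os.PathLike, format: str = "mtx_triplet",
                scale_tag: str = "counts") -> ExpressionMatrix:
    """Read an expression matrix from disk.

    Parameters
    ----------
    path
        For ``mtx_triplet``: the ``.mtx`` file (sidecars found next to it)
        or the directory containing the triplet. For ``dense_tsv``: the
        table file (``.tsv`` or ``.csv``).
    format
        ``mtx_triplet`` or ``dense_tsv``.
    scale_tag
        Scale declared for the values; MTX triplets default to ``counts``.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format == "mtx_triplet":
        if path.is_dir():
            folder, mtx = path, path / "matrix.mtx"
            if not mtx.exists():
                raise FormatError(f"missing matrix.mtx in {folder}")
        else:
            folder, mtx = path.parent, path
        try:
            mat = scipy.io.mmread(str(mtx))
        except Exception as exc:  # header/coordinate defects
            raise FormatError(f"malformed Matrix Market file {mtx}: {exc}") from exc
        values = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float
        )
        gene_ids = _read_ids(_find_sidecar(folder, _SIDE_GENES))
        cell_ids = _read_ids(_find_sidecar(folder, _SIDE_CELLS))
        if len(gene_ids) != values.shape[0] or len(cell_ids) != values.shape[1]:
            raise FormatError(
                f"matrix is {values.shape[0]}x{values.shape[1]} but sidecars "
                f"list {len(gene_ids)} genes / {len(cell_ids)} barcodes"
            )
        return ExpressionMatrix(values, gene_ids, cell_ids, scale_tag)
    if format == "dense_tsv":
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        try:
            frame = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:
            raise FormatError(f"malformed dense table {path}: {exc}") from exc
        if frame.shape[1] == 0:
            raise FormatError(f"dense table {path} has no cell columns")
        return ExpressionMatrix(
            frame.to_numpy(dtype=float),
            [str(g) for g in frame.index],
            [str(c) for c in frame.columns],
            scale_tag,
        )
    raise ValidationError(f"unknown format {format!r}")


def write_matrix(expr: ExpressionMatrix, path: str | os.PathLike,
                 format: str = "mtx_triplet") -> None:
    """Write an expression matrix; inverse of :func:`read_matrix`.

    For ``mtx_triplet``, *path* is a directory that will receive
    ``matrix.mtx``, ``genes.tsv`` and ``barcodes.tsv``.
    """
    path = Path(path)
    if format == "mtx_triplet":
        path.mkdir(parents=True, exist_ok=True)
        sparse = scipy.sparse.coo_matrix(expr.values)
        if expr.scale_tag == "counts" and np.allclose(
            expr.values, np.round(expr.values)
        ):
            sparse = sparse.astype(int)
        scipy.io.mmwrite(str(path / "matrix.mtx"), sparse)
        (path / "genes.tsv").write_text(
            "".join(f"{g}\n" for g in expr.gene_ids), encoding="utf-8"
        )
        (path / "barcodes.tsv").write_text(
            "".join(f"{c}\n" for c in expr.cell_ids), encoding="utf-8"
        )
        return
    if format == "dense_tsv":
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        frame = pd.DataFrame(expr.values, index=expr.gene_ids,
                             columns=expr.cell_ids)
        frame.to_csv(path, sep=sep, float_format="%.17g")
        return
    raise ValidationError(f"unknown format {format!r}")


def write_labels(labels: LabelVector, cell_ids: list[str],
                 path: str | os.PathLike) -> None:
    """Write a two-column TSV ``cell_id<TAB>cluster`` (header included)."""
    if len(labels) != len(cell_ids):
        raise ValidationError(
            f"{len(labels)} labels for {len(cell_ids)} cell ids"
        )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("cell_id\tcluster\n")
        for cid, lab in zip(cell_ids, labels):
            fh.write(f"{cid}\t{lab}\n")


def read_labels(path: str | os.PathLike) -> tuple[LabelVector, list[str]]:
    """Read a labels TSV; returns (labels, cell_ids)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if list(frame.columns[:2]) != ["cell_id", "cluster"]:
        raise FormatError(
            f"labels file {path}: expected header 'cell_id\\tcluster', "
            f"got {list(frame.columns[:2])}"
        )
    return LabelVector(frame["cluster"].to_numpy()), list(frame["cell_id"])
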