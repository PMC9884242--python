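"""Reading and writing expression matrices and cell-label files.

The in-memory container is :class:`ExpressionMatrix`: a dense cells × genes
array with ordered cell/gene identifiers and a ``layer`` tag recording where
the matrix sits in the processing chain (``raw`` counts through ``imputed``).
Supported on-disk formats are MatrixMarket with 10x-style sidecars
(``matrix.mtx`` stored genes × cells next to ``features.tsv``/``genes.tsv``
and ``barcodes.tsv``) and dense CSV/TSV with a gene-id header row and a
cell-id index column.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "LAYERS",
    "ValidationError",
    "ExpressionMatrix",
    "load_matrix",
    "save_matrix",
    "load_labels",
]

#: Ordered processing layers a matrix can carry.
LAYERS = ("raw", "normalized", "log", "scaled", "imputed")


class ValidationError(ValueError):
    """An input violates a documented precondition or invariant."""


def _check_ids(ids: list[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise ValidationError(f"duplicate {what} identifiers: {sorted(set(dups))[:5]}")
    return ids


@dataclass
class ExpressionMatrix:
    """Dense cells × genes expression matrix with identifiers and a layer tag.

    Parameters
    ----------
    values
        Non-negative (for ``raw``) numeric array, rows are cells.
    cell_ids, gene_ids
        Ordered unique identifiers; lengths must match ``values.shape``.
    layer
        One of :data:`LAYERS`. ``raw`` additionally requires integer counts.
    meta
        Free-form annotations (e.g. whether the log transform fired).
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    layer: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError(f"values must be 2-D, got shape {self.values.shape}")
        self.cell_ids = _check_ids(list(self.cell_ids), "cell")
        self.gene_ids = _check_ids(list(self.gene_ids), "gene")
        n, g = self.values.shape
        if n != len(self.cell_ids) or g != len(self.gene_ids):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells × {len(self.gene_ids)} genes"
            )
        if self.layer not in LAYERS:
            raise ValidationError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.layer == "raw" and self.values.size:
            if np.any(self.values < 0):
                raise ValidationError("raw counts must be non-negative")
            if not np.allclose(self.values, np.round(self.values)):
                raise ValidationError("raw counts must be integers")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self, **changes) -> "ExpressionMatrix":
        """Return a copy, optionally replacing fields (dataclasses.replace)."""
        out = replace(self, **changes)
        if "values" not in changes:
            out.values = self.values.copy()
        if "meta" not in changes:
            out.meta = dict(self.meta)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)


def _sidecar_paths(mtx_path: Path) -> tuple[Path, Path]:
    """Locate features/genes and barcodes files next to a .mtx file."""
    d = mtx_path.parent
    feat = None
    for name in ("features.tsv", "genes.tsv", "features.txt", "genes.txt"):
        if (d / name).exists():
            feat = d / name
            break
    bc = d / "barcodes.tsv"
    if not bc.exists() and (d / "barcodes.txt").exists():
        bc = d / "barcodes.txt"
    if feat is None or not bc.exists():
        raise FileNotFoundError(
            f"missing features/barcodes sidecar files alongside {mtx_path}"
        )
    return feat, bc


def _read_id_column(path: Path) -> list[str]:
    df = pd.read_csv(path, sep="\t", header=None)
    return [str(v) for v in df.iloc[:, 0]]


def load_matrix(
    path: str | os.PathLike,
    format: str | None = None,
    orientation: str | None = None,
    layer: str = "raw",
) -> ExpressionMatrix:
    """Load a raw count matrix from MatrixMarket (10x-style) or dense CSV/TSV.

    Parameters
    ----------
    path
        For ``mtx``: the ``.mtx`` file or a directory containing
        ``matrix.mtx`` plus sidecars. For ``csv``/``tsv``: the table file.
    format
        ``mtx``, ``csv`` or ``tsv``; inferred from the path when omitted.
    orientation
        ``cells_by_genes`` or ``genes_by_cells``. Defaults to
        ``genes_by_cells`` for mtx (the 10x convention) and
        ``cells_by_genes`` for csv/tsv.
    layer
        Layer tag for the loaded matrix (default ``raw``, which enforces
        non-negative integer counts).
    """
    path = Path(path)
    if format is None:
        if path.is_dir() or path.suffix == ".mtx":
            format = "mtx"
        elif path.suffix in (".csv",):
            format = "csv"
        elif path.suffix in (".tsv", ".txt"):
            format = "tsv"
        else:
            raise ValidationError(f"cannot infer format from {path}")
    if format not in ("mtx", "csv", "tsv"):
        raise ValidationError(f"unknown format {format!r}")
    if orientation is None:
        orientation = "genes_by_cells" if format == "mtx" else "cells_by_genes"
    if orientation not in ("cells_by_genes", "genes_by_cells"):
        raise ValidationError(f"unknown orientation {orientation!r}")

    if format == "mtx":
        mtx_path = path / "matrix.mtx" if path.is_dir() else path
        if not mtx_path.exists():
            raise FileNotFoundError(f"no such file: {mtx_path}")
        feat_path, bc_path = _sidecar_paths(mtx_path)
        mat = scipy.io.mmread(str(mtx_path))
        values = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float
        )
        row_ids = _read_id_column(feat_path)  # genes in the 10x layout
        col_ids = _read_id_column(bc_path)
        if orientation == "genes_by_cells":
            values = values.T
            cell_ids, gene_ids = col_ids, row_ids
        else:
            cell_ids, gene_ids = row_ids, col_ids
    else:
        if not path.exists():
            raise FileNotFoundError(f"no such file: {path}")
        sep = "," if format == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        values = df.to_numpy(dtype=float)
        if orientation == "genes_by_cells":
            values = values.T
            cell_ids = [str(c) for c in df.columns]
            gene_ids = [str(i) for i in df.index]
        else:
            cell_ids = [str(i) for i in df.index]
            gene_ids = [str(c) for c in df.columns]

    if layer == "raw" and values.size and np.any(values < 0):
        raise ValidationError(f"negative entries in {path}")
    return ExpressionMatrix(values, cell_ids, gene_ids, layer=layer)


def save_matrix(
    mat: ExpressionMatrix, path: str | os.PathLike, format: str = "csv"
) -> None:
    """Write a matrix so that :func:`load_matrix` reproduces it.

    ``mtx`` writes the 10x layout: ``path`` is treated as a directory that
    receives ``matrix.mtx`` (genes × cells), ``features.tsv`` and
    ``barcodes.tsv``; csv/tsv write a single dense table (cells × genes).
    """
    path = Path(path)
    if format == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        sparse = scipy.sparse.coo_matrix(mat.values.T)  # genes × cells on disk
        scipy.io.mmwrite(str(path / "matrix.mtx"), sparse)
        (path / "features.tsv").write_text(
            "".join(f"{g}\n" for g in mat.gene_ids)
        )
        (path / "barcodes.tsv").write_text(
            "".join(f"{c}\n" for c in mat.cell_ids)
        )
    elif format in ("csv", "tsv"):
        path.parent.mkdir(parents=True, exist_ok=True)
        sep = "," if format == "csv" else "\t"
        mat.to_frame().to_csv(path, sep=sep, float_format="%.12g")
    else:
        raise ValidationError(f"unknown format {format!r}")


def load_labels(path: str | os.PathLike, cell_ids: list[str]) -> np.ndarray:
    """Load one categorical label per cell, aligned to ``cell_ids`` order.

    Accepts either a headerless one-label-per-line file (must match the cell
    count and order) or a two-column ``id<sep>label`` table in any order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    rows = []
    for ln in lines:
        sep = "\t" if "\t" in ln else ("," if "," in ln else None)
        rows.append([f.strip() for f in ln.split(sep)] if sep else [ln.strip()])
    widths = {len(r) for r in rows}
    if widths == {1}:
        labels = np.array([r[0] for r in rows])
        if len(labels) != len(cell_ids):
            raise ValidationError(
                f"{len(labels)} labels for {len(cell_ids)} cells in {path}"
            )
        return labels
    if widths == {2}:
        mapping = {r[0]: r[1] for r in rows}
        missing = [c for c in cell_ids if str(c) not in mapping]
        if missing:
            raise ValidationError(f"no label for cell ids {missing[:5]} in {path}")
        return np.array([mapping[str(c)] for c in cell_ids])
    raise ValidationError(f"label file {path} must have 1 or 2 columns")
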