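"""Loading, validation, filtering and transformation of gene expression matrices.

The in-memory container is :class:`ExpressionMatrix` — an m-genes x n-cells
dense matrix with gene/cell identifiers and a flag recording whether the
values are raw or log2(1+x)-transformed.  All filters preserve gene and cell
ordering so that downstream matrices (single-cell networks, degree matrices)
stay positionally aligned with the expression matrix.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class ValidationError(ValueError):
    """Raised when an input matrix violates a structural invariant."""


@dataclass
class ExpressionMatrix:
    """Gene expression matrix: genes as rows, cells as columns.

    Parameters
    ----------
    values
        Dense ``(m, n)`` float array of non-negative expression values
        (raw counts / TPM, or log2-transformed — see ``is_log_transformed``).
    gene_ids, cell_ids
        Unique identifiers for the row and column axes.
    is_log_transformed
        True once :func:`log_transform` has been applied.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    is_log_transformed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        m, n = self.values.shape
        if m != len(self.gene_ids):
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {m} matrix rows"
            )
        if n != len(self.cell_ids):
            raise ValidationError(
                f"{len(self.cell_ids)} cell ids for {n} matrix columns"
            )
        if m < 2 or n < 2:
            raise ValidationError(
                f"need at least 2 genes and 2 cells, got {m} x {n}"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        if np.isnan(self.values).any():
            raise ValidationError("expression matrix contains missing values")
        if (self.values < 0).any():
            bad = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative expression value at gene {self.gene_ids[bad[0]]!r}, "
                f"cell {self.cell_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


def _check_unique(ids: list[str], axis: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {axis} id {i!r}")
        seen.add(i)


def load_expression_matrix(path: str | os.PathLike, format: str | None = None) -> ExpressionMatrix:
    """Read an expression matrix from TSV, CSV or MatrixMarket files.

    TSV/CSV: genes as rows, first column gene ids, header row = cell ids.
    MTX: MatrixMarket coordinate file with sibling ``genes.txt`` and
    ``cells.txt`` (one identifier per line) in the same directory.
    """
    path = os.fspath(path)
    if format is None:
        ext = os.path.splitext(path)[1].lower().lstrip(".")
        format = {"tsv": "tsv", "txt": "tsv", "csv": "csv", "mtx": "mtx"}.get(ext)
        if format is None:
            raise ValueError(f"cannot infer format from {path!r}; pass format=")
    if format == "mtx":
        return _load_mtx(path)
    sep = "\t" if format == "tsv" else ","
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, header=0)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValidationError(f"failed to parse {path!r}: {exc}") from exc
    non_numeric = df.columns[
        [not np.issubdtype(dt, np.number) for dt in df.dtypes]
    ]
    if len(non_numeric):
        raise ValidationError(
            f"non-numeric expression values in column(s) {list(non_numeric)!r}"
        )
    return ExpressionMatrix(
        values=df.to_numpy(dtype=float),
        gene_ids=[str(g) for g in df.index],
        cell_ids=[str(c) for c in df.columns],
        is_log_transformed=False,
    )


def _load_mtx(path: str) -> ExpressionMatrix:
    directory = os.path.dirname(os.path.abspath(path))
    genes_path = os.path.join(directory, "genes.txt")
    cells_path = os.path.join(directory, "cells.txt")
    for p in (genes_path, cells_path):
        if not os.path.exists(p):
            raise ValidationError(f"MTX input requires sibling id file {p!r}")
    mat = scipy.io.mmread(path)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    genes = _read_id_lines(genes_path)
    cells = _read_id_lines(cells_path)
    return ExpressionMatrix(
        values=np.asarray(mat, dtype=float),
        gene_ids=genes,
        cell_ids=cells,
        is_log_transformed=False,
    )


def _read_id_lines(path: str) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_expression_matrix(gem: ExpressionMatrix, path: str | os.PathLike) -> None:
    """Write a TSV with genes as rows (inverse of the TSV loader)."""
    gem.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def filter_low_genes(gem: ExpressionMatrix, min_cells: int = 10) -> ExpressionMatrix:
    """Drop genes expressed (strictly positive) in fewer than ``min_cells`` cells.

    Dropout zeros count as "not expressed".  Operates on the raw matrix; the
    cell axis and the ordering of surviving genes are unchanged.
    """
    if gem.is_log_transformed:
        raise ValidationError("filter_low_genes expects a raw (untransformed) matrix")
    if min_cells < 0:
        raise ValueError("min_cells must be non-negative")
    expressed_cells = (gem.values > 0).sum(axis=1)
    keep = expressed_cells >= min_cells
    if not keep.any():
        raise ValidationError(
            f"no gene is expressed in at least {min_cells} cells"
        )
    return ExpressionMatrix(
        values=gem.values[keep],
        gene_ids=[g for g, k in zip(gem.gene_ids, keep) if k],
        cell_ids=list(gem.cell_ids),
        is_log_transformed=False,
    )


def log_transform(gem: ExpressionMatrix) -> ExpressionMatrix:
    """Replace every entry v by log2(v + 1)."""
    if gem.is_log_transformed:
        raise ValidationError("matrix is already log-transformed")
    return ExpressionMatrix(
        values=np.log2(gem.values + 1.0),
        gene_ids=list(gem.gene_ids),
        cell_ids=list(gem.cell_ids),
        is_log_transformed=True,
    )


def select_top_variable_genes(gem: ExpressionMatrix, k: int) -> ExpressionMatrix:
    """Keep the k most variable genes (population variance across cells).

    Original gene order is preserved.  Ties at the cut are broken in favour
    of the lexicographically smaller gene id, so the selection is
    deterministic.
    """
    m = gem.n_genes
    if k < 1 or k > m:
        raise ValueError(f"k must be in [1, {m}], got {k}")
    variances = gem.values.var(axis=1)
    # sort by (-variance, gene_id) and keep the first k, then restore order
    order = sorted(range(m), key=lambda i: (-variances[i], gem.gene_ids[i]))
    keep = np.zeros(m, dtype=bool)
    keep[order[:k]] = True
    return ExpressionMatrix(
        values=gem.values[keep],
        gene_ids=[g for g, kp in zip(gem.gene_ids, keep) if kp],
        cell_ids=list(gem.cell_ids),
        is_log_transformed=gem.is_log_transformed,
    )


def load_labels(path: str | os.PathLike, cell_ids: list[str] | None = None) -> list[str]:
    """Read a two-column (cell_id, label) TSV; returns labels in cell order.

    If ``cell_ids`` is given, labels are reordered to match it and every cell
    must be present.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["cell_id", "label"],
                     dtype=str, comment="#")
    mapping = dict(zip(df["cell_id"], df["label"]))
    if cell_ids is None:
        return list(df["label"])
    missing = [c for c in cell_ids if c not in mapping]
    if missing:
        raise ValidationError(f"labels missing for cells {missing[:5]!r}")
    return [mapping[c] for c in cell_ids]
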