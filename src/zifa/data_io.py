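"""Reading, writing and filtering of log-expression matrices.

The internal convention throughout the package is *cells by genes*: an
``ExpressionMatrix`` holds an ``N x D`` array of log read counts for ``N``
cells and ``D`` genes, with exact zeros marking candidate dropout events.
Files laid out genes-in-rows are transposed on read.

Supported on-disk formats:

* CSV / TSV with a header row and an index column (labels required);
* MatrixMarket coordinate format plus two one-column label files
  (row labels, column labels).

No normalisation or count-level preprocessing happens here; values are
assumed to be log-transformed already.  An explicit ``log1p`` flag is the
only transform offered, and it is never applied silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

Orientation = Literal["cells_by_genes", "genes_by_cells"]

__all__ = [
    "ExpressionMatrix",
    "read_matrix",
    "write_matrix",
    "filter_genes",
]


class ValidationError(ValueError):
    """Raised when a matrix violates the expression-matrix contract."""


@dataclass
class ExpressionMatrix:
    """Labelled N x D matrix of log read counts (cells in rows).

    Parameters
    ----------
    values
        ``(N, D)`` float array; finite, non-negative.  Exact zeros are
        candidate dropout events and are preserved exactly.
    cell_ids, gene_ids
        Unique row / column labels.
    orientation_tag
        Layout of the *source* file this matrix was read from; purely a
        provenance record, the in-memory layout is always cells-by-genes.
    """

    values: np.ndarray
    cell_ids: Sequence[str]
    gene_ids: Sequence[str]
    orientation_tag: Orientation = "cells_by_genes"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = list(map(str, self.cell_ids))
        self.gene_ids = list(map(str, self.gene_ids))
        v = self.values
        if v.ndim != 2:
            raise ValidationError(f"expected a 2-D matrix, got shape {v.shape}")
        n, d = v.shape
        if n < 2 or d < 1:
            raise ValidationError(
                f"need at least 2 cells and 1 gene, got {n} cells x {d} genes"
            )
        if len(self.cell_ids) != n or len(self.gene_ids) != d:
            raise ValidationError("label lengths do not match matrix shape")
        if len(set(self.cell_ids)) != n:
            raise ValidationError("duplicate cell labels")
        if len(set(self.gene_ids)) != d:
            raise ValidationError("duplicate gene labels")
        if not np.all(np.isfinite(v)):
            raise ValidationError("matrix contains non-finite entries")
        if np.any(v < 0):
            i, j = np.argwhere(v < 0)[0]
            raise ValidationError(
                f"negative entry at cell {self.cell_ids[i]!r}, "
                f"gene {self.gene_ids[j]!r}: log read counts must be >= 0"
            )

    # -- convenience ---------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def zero_mask(self) -> np.ndarray:
        """Boolean (N, D) mask of exact zeros (candidate dropouts)."""
        return self.values == 0.0

    def zero_fraction_per_gene(self) -> np.ndarray:
        return self.zero_mask().mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.values.shape == other.values.shape
            and np.array_equal(self.values, other.values)
            and self.cell_ids == other.cell_ids
            and self.gene_ids == other.gene_ids
        )


def _read_labels(path: Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_matrix(
    path: str | Path,
    format: Literal["csv", "tsv", "mtx"] | None = None,
    orientation: Orientation = "cells_by_genes",
    *,
    row_labels: str | Path | None = None,
    col_labels: str | Path | None = None,
    log1p: bool = False,
) -> ExpressionMatrix:
    """Read an expression matrix from CSV, TSV or MatrixMarket.

    Parameters
    ----------
    path
        File to read.  ``format`` defaults from the suffix.
    orientation
        Layout of the file: ``genes_by_cells`` files are transposed so the
        returned matrix is always cells-by-genes.
    row_labels, col_labels
        Companion one-column label files, required for ``mtx`` (MatrixMarket
        carries no labels).  Labels refer to the *file's* rows/columns, in
        the file's own orientation.
    log1p
        If True, apply ``log(1 + v)`` to the values after reading.  Never
        applied by default: input is assumed to be log-transformed already.

    Notes
    -----
    Zeros are preserved exactly; absent entries of a sparse MatrixMarket
    file materialise as ``0.0``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        suffix = path.suffix.lower().lstrip(".")
        format = {"csv": "csv", "tsv": "tsv", "txt": "tsv", "mtx": "mtx"}.get(suffix)
        if format is None:
            raise ValueError(f"cannot infer format from suffix of {path.name!r}")

    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except pd.errors.ParserError as exc:
            raise ValueError(f"malformed {format} file {path.name!r}: {exc}") from exc
        rows = [str(r) for r in df.index]
        # pandas de-duplicates repeated header names (g1 -> g1.1); take the
        # labels from the raw header line so duplicates are caught
        with open(path) as fh:
            header = fh.readline().rstrip("\n\r").split(sep)[1:]
        cols = [str(c) for c in header]
        if len(cols) != df.shape[1]:  # pragma: no cover - malformed header
            cols = [str(c) for c in df.columns]
        values = df.to_numpy(dtype=float)
    elif format == "mtx":
        if row_labels is None or col_labels is None:
            raise ValueError("MTX input requires row_labels and col_labels files")
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        values = np.asarray(mat, dtype=float)
        rows = _read_labels(Path(row_labels))
        cols = _read_labels(Path(col_labels))
        if len(rows) != values.shape[0] or len(cols) != values.shape[1]:
            raise ValidationError(
                f"label files ({len(rows)} rows, {len(cols)} cols) do not match "
                f"matrix shape {values.shape}"
            )
    else:  # pragma: no cover - guarded above
        raise ValueError(f"unknown format {format!r}")

    if orientation == "genes_by_cells":
        values = values.T
        cell_ids, gene_ids = cols, rows
    else:
        cell_ids, gene_ids = rows, cols

    if log1p:
        if np.any(values < 0):
            raise ValidationError("log1p requested but matrix has negative entries")
        values = np.log1p(values)

    return ExpressionMatrix(values, cell_ids, gene_ids, orientation_tag=orientation)


def write_matrix(
    m: ExpressionMatrix,
    path: str | Path,
    format: Literal["csv", "tsv"] | None = None,
) -> None:
    """Write cells-by-genes CSV/TSV with full round-trip fidelity.

    Uses ``repr`` float formatting so that ``read_matrix(write_matrix(m))``
    reproduces ``m`` bit-exactly for finite values.
    """
    path = Path(path)
    if format is None:
        format = "tsv" if path.suffix.lower() in (".tsv", ".txt") else "csv"
    sep = "," if format == "csv" else "\t"
    m.to_frame().to_csv(path, sep=sep, float_format=None)


def filter_genes(
    m: ExpressionMatrix, max_zero_fraction: float = 0.95
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop genes whose zero fraction exceeds ``max_zero_fraction``.

    Very sparse genes carry little signal for imputation and can destabilise
    the EM fit, so the customary preprocessing step is to remove genes that
    are zero in more than 95 % of cells (an 80 % threshold for stubborn data
    sets).  Genes that are zero everywhere are always removed, whatever the
    threshold: imputing a gene with no observed expression cannot recover
    information.

    Returns the filtered matrix (gene order preserved) and the list of
    removed gene ids.  Idempotent at a fixed threshold.
    """
    if not 0.0 < max_zero_fraction <= 1.0:
        raise ValueError("max_zero_fraction must be in (0, 1]")
    frac = m.zero_fraction_per_gene()
    keep = (frac <= max_zero_fraction) & (frac < 1.0)
    if not keep.any():
        raise ValidationError(
            "all genes removed by the zero-fraction filter; relax "
            f"max_zero_fraction (currently {max_zero_fraction})"
        )
    removed = [g for g, k in zip(m.gene_ids, keep) if not k]
    if not removed:
        return m, []
    kept = ExpressionMatrix(
        m.values[:, keep],
        m.cell_ids,
        [g for g, k in zip(m.gene_ids, keep) if k],
        orientation_tag=m.orientation_tag,
    )
    return kept, removed
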