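"""Delimited-text and Matrix Market readers/writers.

Expression data travels as TSV/CSV with ids in the first column and a
header row; the orientation flag accepts gene-in-rows files and always
hands back the internal n x p samples-by-genes layout.  Design and
contrast matrices are plain delimited numeric tables with no header
requirement.  Sparse symmetric matrices (zero patterns, fitted precisions)
use Matrix Market coordinate format with symmetric storage (lower
triangle), 1-based on disk and 0-based in memory.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .core import DesignMatrix, ExpressionMatrix
from .pattern import ZeroPattern
from .precision import SparsePrecision

__all__ = [
    "read_expression",
    "read_design",
    "read_table_matrix",
    "write_expression",
    "write_sparse_symmetric",
    "read_sparse_symmetric",
    "read_pattern",
    "read_precision",
]


def _detect_sep(path) -> str:
    """Pick the delimiter from the first line: tab, comma, semicolon, or
    whitespace.  (csv.Sniffer misfires on single-column numeric files.)"""
    with open(path) as fh:
        first = fh.readline()
    for sep in ("\t", ",", ";"):
        if sep in first:
            return sep
    return r"\s+"


def _read_frame(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=_detect_sep(path), engine="python",
                       index_col=0)


def read_expression(path, genes_in_rows: bool = False) -> ExpressionMatrix:
    """Read a delimited expression table into samples x genes layout.

    The first column holds sample ids (or gene ids when
    ``genes_in_rows=True``); the header row holds the other axis' ids.
    Non-numeric or missing cells are reported with their coordinates;
    duplicate gene ids are rejected.
    """
    df = _read_frame(path)
    if genes_in_rows:
        df = df.T
    bad = df.isna()
    if bad.any().any():
        i, j = np.argwhere(bad.values)[0]
        raise ValueError(
            f"{path}: missing or non-numeric value for sample "
            f"{df.index[i]!r}, gene {df.columns[j]!r}"
        )
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        for j, col in enumerate(df.columns):
            try:
                df[col].astype(float)
            except (TypeError, ValueError):
                i = df[col].apply(
                    lambda v: not isinstance(v, (int, float))).idxmax()
                raise ValueError(
                    f"{path}: non-numeric cell at row {i!r}, column {col!r}"
                ) from exc
        raise
    return ExpressionMatrix(values, sample_ids=list(df.index.astype(str)),
                            gene_ids=list(df.columns.astype(str)))


def write_expression(path, X: ExpressionMatrix) -> None:
    df = pd.DataFrame(X.values, index=X.sample_ids, columns=X.gene_ids)
    df.to_csv(path, sep="\t", index_label="sample")


def read_table_matrix(path) -> np.ndarray:
    """Numeric delimited matrix, header optional; row order = sample order."""
    raw = pd.read_csv(path, sep=_detect_sep(path), engine="python",
                      header=None)
    first = raw.iloc[0]
    has_header = any(
        isinstance(v, str) and not _is_number(v) for v in first
    )
    if has_header:
        raw = raw.iloc[1:]
    try:
        return raw.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric entries in matrix") from exc


def _is_number(s) -> bool:
    try:
        float(s)
        return True
    except (TypeError, ValueError):
        return False


def read_design(path, column_labels=None) -> DesignMatrix:
    return DesignMatrix(read_table_matrix(path), column_labels=column_labels)


def write_sparse_symmetric(path, M) -> None:
    """Matrix Market coordinate file, symmetric storage (lower triangle)."""
    if isinstance(M, SparsePrecision):
        M = M.K
    elif isinstance(M, ZeroPattern):
        M = M.N
    M = sp.csr_matrix(M)
    if M.shape[0] != M.shape[1]:
        raise ValueError("matrix must be square")
    gap = abs(M - M.T)
    if gap.nnz and gap.max() > 1e-12 * max(abs(M).max(), 1.0):
        raise ValueError("matrix is not symmetric; refusing symmetric storage")
    scipy.io.mmwrite(str(path), sp.tril(M), symmetry="symmetric")


def read_sparse_symmetric(path) -> sp.csr_matrix:
    M = scipy.io.mmread(str(path))
    return sp.csr_matrix(M)


def read_pattern(path) -> ZeroPattern:
    return ZeroPattern(read_sparse_symmetric(path))


def read_precision(path) -> SparsePrecision:
    return SparsePrecision(read_sparse_symmetric(path))
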