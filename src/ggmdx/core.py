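"""Model containers and mean-structure estimation.

The data model is a matrix-normal linear model for an n x p expression
matrix X (samples x genes): vec(X) ~ N(vec(D B), I (x) Sigma), where D is an
n x r design matrix, B an r x p matrix of treatment effects and Sigma the
common p x p covariance of the gene expression vector of a sample.  Each row
of X is multivariate normal with mean D_i. B and covariance Sigma; each
column is an ordinary regression on D with i.i.d. errors.

This module provides the containers for X, D and B, ordinary-least-squares
estimation of B (which is the maximum-likelihood estimate regardless of
Sigma), residuals under a sub-model, and on-demand access to entries of the
sample covariance S = R' R / n without ever materialising the dense p x p
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg


__all__ = [
    "ExpressionMatrix",
    "DesignMatrix",
    "CoefficientMatrix",
    "SampleCov",
    "ResidualBundle",
    "RankDeficientDesignError",
    "estimate_coefficients",
    "residuals_under",
    "sample_cov_entry",
]


class RankDeficientDesignError(ValueError):
    """Design matrix does not have full column rank."""

    def __init__(self, dependent_columns, labels=None):
        self.dependent_columns = list(dependent_columns)
        if labels is not None:
            names = [labels[j] for j in self.dependent_columns]
        else:
            names = [str(j) for j in self.dependent_columns]
        super().__init__(
            "design matrix is rank deficient; columns linearly dependent on "
            "earlier columns: " + ", ".join(names)
        )


def _as_2d_float(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be a 2-D matrix, got shape {arr.shape}")
    if not np.isfinite(arr).all():
        bad = np.argwhere(~np.isfinite(arr))[0]
        raise ValueError(
            f"{name} contains a non-finite value at row {bad[0]}, column {bad[1]}"
        )
    return arr


@dataclass
class ExpressionMatrix:
    """n x p expression data, rows = samples, columns = genes."""

    values: np.ndarray
    sample_ids: list[str] | None = None
    gene_ids: list[str] | None = None

    def __post_init__(self):
        self.values = _as_2d_float(self.values, "expression matrix")
        n, p = self.values.shape
        if n < 2:
            raise ValueError(f"need at least 2 samples, got {n}")
        if self.sample_ids is None:
            self.sample_ids = [f"sample{i}" for i in range(n)]
        if self.gene_ids is None:
            self.gene_ids = [f"gene{j}" for j in range(p)]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match number of rows")
        if len(self.gene_ids) != p:
            raise ValueError("gene_ids length does not match number of columns")
        if len(set(self.gene_ids)) != p:
            dup = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValueError(f"duplicate gene ids: {dup[:5]}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class DesignMatrix:
    """n x r design matrix; rows aligned with the expression samples."""

    values: np.ndarray
    column_labels: list[str] | None = None

    def __post_init__(self):
        self.values = _as_2d_float(self.values, "design matrix")
        n, r = self.values.shape
        if self.column_labels is None:
            self.column_labels = [f"d{j}" for j in range(r)]
        self.column_labels = [str(c) for c in self.column_labels]
        if len(self.column_labels) != r:
            raise ValueError("column_labels length does not match design columns")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.values))

    def check_full_rank(self) -> None:
        _qr_full_rank(self.values, self.column_labels)


@dataclass
class CoefficientMatrix:
    """r x p matrix of treatment effects (one column per gene)."""

    values: np.ndarray
    row_labels: list[str] | None = None
    gene_ids: list[str] | None = None

    def __post_init__(self):
        self.values = _as_2d_float(self.values, "coefficient matrix")


def _qr_full_rank(D: np.ndarray, labels=None):
    """QR of D, raising RankDeficientDesignError with the offending columns."""
    n, r = D.shape
    if r > n:
        raise RankDeficientDesignError(list(range(n, r)), labels)
    Q, Rm = np.linalg.qr(D)
    diag = np.abs(np.diag(Rm))
    scale = max(np.abs(Rm).max(), 1.0)
    bad = np.nonzero(diag <= scale * n * np.finfo(float).eps * 10)[0]
    if bad.size:
        raise RankDeficientDesignError(bad, labels)
    return Q, Rm


def _design_values(D) -> tuple[np.ndarray, list | None]:
    if isinstance(D, DesignMatrix):
        return D.values, D.column_labels
    return _as_2d_float(D, "design matrix"), None


def _expr_values(X) -> np.ndarray:
    if isinstance(X, ExpressionMatrix):
        return X.values
    return _as_2d_float(X, "expression matrix")


def estimate_coefficients(X, D) -> CoefficientMatrix:
    """Maximum-likelihood estimate B_hat = (D'D)^{-1} D'X, computed via QR.

    Column j of the result is the OLS regression of gene j on the design;
    under the matrix-normal model this is the MLE of B for any Sigma.
    """
    Xv = _expr_values(X)
    Dv, labels = _design_values(D)
    if Xv.shape[0] != Dv.shape[0]:
        raise ValueError(
            f"X has {Xv.shape[0]} samples but D has {Dv.shape[0]} rows"
        )
    Q, Rm = _qr_full_rank(Dv, labels)
    B = scipy.linalg.solve_triangular(Rm, Q.T @ Xv)
    gene_ids = X.gene_ids if isinstance(X, ExpressionMatrix) else None
    return CoefficientMatrix(B, row_labels=labels, gene_ids=gene_ids)


class SampleCov:
    """On-demand entries of S = R'R / n for a residual matrix R.

    Never materialises the dense p x p matrix; callers ask for single
    entries or small blocks (e.g. clique submatrices).  The maximum
    likelihood divisor n is used throughout.
    """

    def __init__(self, R: np.ndarray):
        self.R = np.asarray(R, dtype=float)
        self.n, self.p = self.R.shape

    def entry(self, i: int, j: int) -> float:
        return float(self.R[:, i] @ self.R[:, j]) / self.n

    def block(self, rows, cols=None) -> np.ndarray:
        rows = np.asarray(rows, dtype=int)
        cols = rows if cols is None else np.asarray(cols, dtype=int)
        return (self.R[:, rows].T @ self.R[:, cols]) / self.n

    def diagonal(self) -> np.ndarray:
        return np.einsum("ij,ij->j", self.R, self.R) / self.n

    def dense(self) -> np.ndarray:
        """Full S; only for small p (tests, small analyses)."""
        return (self.R.T @ self.R) / self.n


@dataclass
class ResidualBundle:
    """Residuals R = X - F_hat under a (sub-)model and their sample covariance."""

    residuals: np.ndarray
    fitted: np.ndarray
    sample_cov: SampleCov = field(init=False)

    def __post_init__(self):
        self.sample_cov = SampleCov(self.residuals)


def residuals_under(X, D_sub) -> ResidualBundle:
    """Project X on the column space of D_sub; return residuals and fit.

    F_hat = D_sub (D_sub'D_sub)^{-1} D_sub' X is the orthogonal projection,
    so R'D_sub = 0 up to rounding.  An empty design (0 columns) means a
    zero-mean null model: F_hat = 0, R = X.
    """
    Xv = _expr_values(X)
    Dv, labels = _design_values(D_sub)
    if Dv.shape[1] == 0:
        return ResidualBundle(Xv.copy(), np.zeros_like(Xv))
    if Xv.shape[0] != Dv.shape[0]:
        raise ValueError("X and D_sub have different numbers of rows")
    Q, _ = _qr_full_rank(Dv, labels)
    F = Q @ (Q.T @ Xv)
    return ResidualBundle(Xv - F, F)


def sample_cov_entry(R: np.ndarray, i: int, j: int) -> float:
    """(R'R)_{ij} / n for a residual matrix R."""
    R = np.asarray(R, dtype=float)
    n, p = R.shape
    if not (0 <= i < p and 0 <= j < p):
        raise IndexError(f"gene index out of range for p={p}")
    return float(R[:, i] @ R[:, j]) / n


# -- small vec/kron helpers (row-major stacking convention) ------------------

def vec(X: np.ndarray) -> np.ndarray:
    """Stack rows of X into a vector (row-major vec)."""
    return np.asarray(X).reshape(-1)


def vecc(X: np.ndarray) -> np.ndarray:
    """Stack columns of X into a vector; vec(X) == vecc(X')."""
    return np.asarray(X).T.reshape(-1)
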