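"""Sparse symmetric factorisation helpers.

SciPy has no sparse Cholesky, but SuperLU in symmetric mode (zero
diagonal-pivot threshold, symmetric fill-reducing ordering) keeps its row
and column permutations equal, so it computes P K P' = L U with unit-lower
L and U = D L', i.e. an LDL' factorisation of a symmetric permutation of
K.  Congruence preserves inertia, so diag(U) > 0 is exactly positive
definiteness, sum(log diag U) is the log-determinant, and with
y = U^{-1} sqrt(d) z for i.i.d. standard normals z, x = y[perm] is a draw
from N(0, K^{-1}).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu, spsolve_triangular

__all__ = [
    "ldl_factor",
    "is_positive_definite",
    "sparse_cholesky_logdet",
    "sample_gaussian_from_precision",
]


class _LDLFactor:
    """U (upper factor of the permuted matrix), its diagonal d, and the
    symmetric permutation perm with K[i, j] = (L D L')[perm[i], perm[j]]."""

    def __init__(self, U: sp.csr_matrix, perm: np.ndarray):
        self.U = U
        self.d = U.diagonal()
        self.perm = perm


def ldl_factor(K) -> _LDLFactor | None:
    """LDL' of symmetric K via SuperLU symmetric mode; None if not PD.

    Returns None when a non-positive pivot appears (indefinite), when the
    matrix is exactly singular, or (defensively) when off-diagonal pivoting
    broke the symmetric permutation.
    """
    Kc = sp.csc_matrix(K, dtype=float)
    try:
        f = splu(Kc, permc_spec="MMD_AT_PLUS_A", diag_pivot_thresh=0.0,
                 options=dict(SymmetricMode=True))
    except RuntimeError:  # exactly singular
        return None
    if not (f.perm_r == f.perm_c).all():
        return None
    U = f.U.tocsr()
    d = U.diagonal()
    if not np.isfinite(d).all() or (d <= 0).any():
        return None
    return _LDLFactor(U, np.asarray(f.perm_r))


def is_positive_definite(K) -> bool:
    return ldl_factor(K) is not None


def sparse_cholesky_logdet(K) -> float:
    f = ldl_factor(K)
    if f is None:
        raise ValueError("matrix is not positive definite")
    return float(np.log(f.d).sum())


def sample_gaussian_from_precision(K, n: int, rng: np.random.Generator,
                                   ) -> np.ndarray:
    """n i.i.d. rows from N(0, K^{-1}) without forming K^{-1}.

    One triangular solve handles all samples at once; a dense Cholesky is
    the fallback if the sparse factorisation is unavailable.
    """
    Kc = sp.csc_matrix(K, dtype=float)
    p = Kc.shape[0]
    z = rng.standard_normal((p, n))
    f = ldl_factor(Kc)
    if f is not None:
        Y = spsolve_triangular(f.U, np.sqrt(f.d)[:, None] * z, lower=False)
        return Y[f.perm].T
    L = np.linalg.cholesky(Kc.toarray())
    # K = L L' -> covariance K^{-1} achieved by solving L' x = z
    import scipy.linalg
    X = scipy.linalg.solve_triangular(L.T, z, lower=False)
    return X.T
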