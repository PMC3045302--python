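"""Multivariate contrast tests with DE / DC decomposition.

A hypothesis about the treatment effects, C'B = 0 for an r x s contrast
matrix C, is reparameterised through an orthogonal completion Q = [A C]:
with D~ = DQ and Gamma = Q'B the hypothesis becomes Gamma_2 = 0 for the
last s rows of Gamma.  Conditional on the fitted precision K = Sigma^{-1},
the test statistic is

    T = trace{(G^22)^{-1} Gamma2_hat K Gamma2_hat'}
      = trace(Gamma2_tilde K Gamma2_tilde'),   Gamma2_tilde = L' Gamma2_hat,

where G^22 is the (2,2) block of (D~'D~)^{-1} and L L' = (G^22)^{-1}.  Each
contrast row gamma decomposes gene by gene as

    gamma' K gamma = sum_i  K_ii * gamma_i * (gamma_N)_i,
    (gamma_N)_i = gamma_i - sum_{j in n(i)} beta_ij gamma_j,

so T splits into a differential-expression part (is gamma_i large?) and a
differential-connection part (does gamma_i deviate from the weighted
combination of its neighbours' contrasts?).  Significance comes from a
residual-permutation null: fit the null mean model, permute residual rows,
rebuild the data and recompute everything; the precision is held fixed
across permutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .core import DesignMatrix, ExpressionMatrix, _design_values, _expr_values, _qr_full_rank
from .precision import SparsePrecision

__all__ = [
    "ContrastFrame",
    "TestResult",
    "MultiplicityResult",
    "orthogonal_complete",
    "build_frame",
    "statistic_T",
    "permutation_null",
    "modified_bonferroni",
    "two_group_design",
    "two_group_test",
]


def orthogonal_complete(C, r: int | None = None) -> np.ndarray:
    """Expand a contrast matrix C (r x s) into orthogonal Q = [A C].

    C must have full column rank; if its columns are not already
    orthonormal they are orthonormalised first (the hypothesis C'B = 0 is
    unchanged by invertible column operations).  The complement A is the
    orthonormal basis of the orthogonal complement, with a deterministic
    sign convention (largest-magnitude entry of each column positive).
    """
    C = np.atleast_2d(np.asarray(C, dtype=float))
    if C.shape[0] == 1 and (r is None or r != 1):
        C = C.T
    r_, s = C.shape
    if r is not None and r != r_:
        raise ValueError(f"C has {r_} rows, expected r={r}")
    r = r_
    if s >= r:
        raise ValueError(f"need s < r contrasts, got s={s}, r={r}")
    Qc, Rc = np.linalg.qr(C)
    if np.abs(np.diag(Rc)).min() <= 1e-10 * max(np.abs(Rc).max(), 1.0):
        raise ValueError("contrast matrix is rank deficient")
    if np.allclose(C.T @ C, np.eye(s), atol=1e-10):
        C_orth = C
    else:
        # fix signs so the orthonormalised contrasts point like the originals
        C_orth = Qc * np.sign(np.diag(Rc))
    Qfull, _ = np.linalg.qr(C_orth, mode="complete")
    A = Qfull[:, s:]
    # deterministic signs for the complement columns
    idx = np.argmax(np.abs(A), axis=0)
    signs = np.sign(A[idx, np.arange(A.shape[1])])
    signs[signs == 0] = 1.0
    A = A * signs
    Q = np.hstack([A, C_orth])
    return Q


@dataclass
class ContrastFrame:
    """Reparameterised design and estimates for a contrast hypothesis."""

    D: np.ndarray
    C: np.ndarray
    Q: np.ndarray
    D_tilde: np.ndarray
    D_tilde_1: np.ndarray
    Gamma_hat: np.ndarray
    Gamma2_hat: np.ndarray
    G22: np.ndarray
    L: np.ndarray          # L L' = (G22)^{-1}
    W: np.ndarray = field(repr=False, default=None)  # (D~'D~)^{-1} D~'

    @property
    def s(self) -> int:
        return self.C.shape[1]

    @property
    def Gamma2_tilde(self) -> np.ndarray:
        return self.L.T @ self.Gamma2_hat


def build_frame(X, D, C) -> ContrastFrame:
    """Build the reparameterised frame for testing C'B = 0.

    Gamma_hat = (D~'D~)^{-1} D~'X with D~ = DQ; under the null the last s
    rows Gamma2_hat have mean zero with row covariance G22 (x) Sigma, where
    G22 is the lower-right s x s block of (D~'D~)^{-1}.
    """
    Xv = _expr_values(X)
    Dv, labels = _design_values(D)
    _qr_full_rank(Dv, labels)
    C = np.atleast_2d(np.asarray(C, dtype=float))
    r = Dv.shape[1]
    if C.shape[0] != r:
        C = C.T
    if C.shape[0] != r:
        raise ValueError("contrast matrix does not conform to the design")
    s = C.shape[1]
    Q = orthogonal_complete(C, r)
    C_orth = Q[:, r - s:]
    Dt = Dv @ Q
    M = Dt.T @ Dt
    Minv = np.linalg.inv(M)
    W = Minv @ Dt.T
    Gamma_hat = W @ Xv
    G22 = Minv[r - s:, r - s:]
    G22 = (G22 + G22.T) * 0.5
    L = np.linalg.cholesky(np.linalg.inv(G22))
    return ContrastFrame(
        D=Dv, C=C_orth, Q=Q, D_tilde=Dt, D_tilde_1=Dt[:, : r - s],
        Gamma_hat=Gamma_hat, Gamma2_hat=Gamma_hat[r - s:], G22=G22, L=L, W=W,
    )


def _precision_csr(K) -> sp.csr_matrix:
    if isinstance(K, SparsePrecision):
        return K.K
    return sp.csr_matrix(K, dtype=float)


def _decompose(Gamma2_tilde: np.ndarray, Kc: sp.csr_matrix):
    """Per-gene decomposition of T = trace(G~ K G~').

    Returns (T, gamma_nb, components): gamma_nb[k, i] = (gamma_N)_i for
    contrast row k; components[i] = sum_k K_ii gamma_ki (gamma_N)_ki, so
    T = components.sum().
    """
    U = (Kc @ Gamma2_tilde.T).T          # rows: (K gamma)' = K_ii (gamma_N)_i
    d = Kc.diagonal()
    gamma_nb = U / d
    components = np.einsum("ki,ki->i", Gamma2_tilde, U)
    T = float(components.sum())
    return T, gamma_nb, components


@dataclass
class TestResult:
    """Observed statistic, per-gene decomposition, and permutation nulls."""

    T_obs: float
    gamma_raw: np.ndarray        # Gamma2_hat, s x p
    gamma: np.ndarray            # Gamma2_tilde = L' Gamma2_hat, s x p
    gamma_nb: np.ndarray         # neighbour-corrected (gamma_N), s x p
    components: np.ndarray       # per-gene sum_k K_ii gamma (gamma_N), length p
    de_stat: np.ndarray = None
    dc_stat: np.ndarray = None
    null_T: np.ndarray = None
    null_de: np.ndarray = None   # q x p
    null_dc: np.ndarray = None   # q x p
    pvalue_T: float = None
    pvalues_de: np.ndarray = None
    pvalues_dc: np.ndarray = None
    n_perm: int = 0
    gene_ids: list[str] | None = None


def _per_gene_stats(Gamma2_tilde, gamma_nb, Kc):
    """DE and DC statistics per gene.

    For a single contrast row these are gamma_i and (gamma_N)_i, tested
    two-sided.  For s > 1 the per-gene quantities are summed over contrast
    rows following the trace structure: DE = sum_k gamma_ki^2 and DC = the
    summed component K_ii sum_k gamma_ki (gamma_N)_ki.
    """
    s = Gamma2_tilde.shape[0]
    if s == 1:
        return Gamma2_tilde[0].copy(), gamma_nb[0].copy()
    de = np.einsum("ki,ki->i", Gamma2_tilde, Gamma2_tilde)
    d = Kc.diagonal()
    dc = d * np.einsum("ki,ki->i", Gamma2_tilde, gamma_nb)
    return de, dc


def statistic_T(frame: ContrastFrame, K) -> TestResult:
    """Observed multivariate statistic and its per-gene DE/DC decomposition."""
    Kc = _precision_csr(K)
    if Kc.shape[0] != frame.Gamma2_hat.shape[1]:
        raise ValueError("precision dimension does not match the data")
    Gt = frame.Gamma2_tilde
    T, gamma_nb, components = _decompose(Gt, Kc)
    de, dc = _per_gene_stats(Gt, gamma_nb, Kc)
    return TestResult(T_obs=T, gamma_raw=frame.Gamma2_hat.copy(), gamma=Gt,
                      gamma_nb=gamma_nb, components=components,
                      de_stat=de, dc_stat=dc)


def permutation_null(X, D, C, K, q: int, seed, *, frame: ContrastFrame | None = None,
                     ) -> TestResult:
    """Residual-permutation null for T and its per-gene components.

    Procedure: fit the null mean model (design restricted to D~1), take
    residuals R = X - F_hat, and for each of q draws rebuild
    X(k) = F_hat + P_k R with a uniformly random row permutation P_k,
    recompute Gamma2_hat(k) and all statistics.  The precision K is held
    fixed.  Empirical p-values use the add-one convention
    (1 + #{null >= obs}) / (q + 1); per-gene tests are two-sided via
    absolute values.  Same seed -> identical nulls.
    """
    if q < 1:
        raise ValueError("need at least one permutation")
    Xv = _expr_values(X)
    if frame is None:
        frame = build_frame(X, D, C)
    Kc = _precision_csr(K)
    res = statistic_T(frame, Kc)
    n = Xv.shape[0]
    D1 = frame.D_tilde_1
    if D1.shape[1]:
        Q1, _ = np.linalg.qr(D1)
        F = Q1 @ (Q1.T @ Xv)
    else:
        F = np.zeros_like(Xv)
    R = Xv - F
    W2 = frame.W[frame.W.shape[0] - frame.s:]   # rows of (D~'D~)^{-1}D~' for Gamma2
    WF = W2 @ F
    rng = np.random.default_rng(seed)
    p = Xv.shape[1]
    null_T = np.empty(q)
    null_de = np.empty((q, p))
    null_dc = np.empty((q, p))
    for k in range(q):
        perm = rng.permutation(n)
        G2k = WF + W2 @ R[perm]
        Gt_k = frame.L.T @ G2k
        Tk, gnb_k, _ = _decompose(Gt_k, Kc)
        de_k, dc_k = _per_gene_stats(Gt_k, gnb_k, Kc)
        null_T[k] = Tk
        null_de[k] = de_k
        null_dc[k] = dc_k
    res.null_T = null_T
    res.null_de = null_de
    res.null_dc = null_dc
    res.n_perm = q
    res.pvalue_T = float((1 + (null_T >= res.T_obs).sum()) / (q + 1))
    if frame.s == 1:
        res.pvalues_de = (1 + (np.abs(null_de) >= np.abs(res.de_stat)).sum(0)) / (q + 1)
        res.pvalues_dc = (1 + (np.abs(null_dc) >= np.abs(res.dc_stat)).sum(0)) / (q + 1)
    else:
        res.pvalues_de = (1 + (null_de >= res.de_stat).sum(0)) / (q + 1)
        res.pvalues_dc = (1 + (np.abs(null_dc) >= np.abs(res.dc_stat)).sum(0)) / (q + 1)
    if isinstance(X, ExpressionMatrix):
        res.gene_ids = list(X.gene_ids)
    return res


@dataclass
class MultiplicityResult:
    """Modified Bonferroni: reject p < alpha/m with alpha allowed above 1,
    bounding the expected number of false rejections by alpha."""

    alpha_expected_fp: float
    m_tests: int
    threshold: float
    rejected_de: np.ndarray
    rejected_dc: np.ndarray


def modified_bonferroni(pvalues_de, pvalues_dc=None, *,
                        alpha_expected_fp: float, m_tests: int | None = None,
                        ) -> MultiplicityResult:
    """Single threshold alpha/m over the union family of DE and DC tests."""
    if alpha_expected_fp <= 0:
        raise ValueError("alpha must be positive")
    p_de = np.asarray(pvalues_de, dtype=float)
    p_dc = None if pvalues_dc is None else np.asarray(pvalues_dc, dtype=float)
    if m_tests is None:
        m_tests = p_de.size + (p_dc.size if p_dc is not None else 0)
    thr = alpha_expected_fp / m_tests
    rej_de = np.nonzero(p_de < thr)[0]
    rej_dc = np.nonzero(p_dc < thr)[0] if p_dc is not None else np.array([], int)
    return MultiplicityResult(alpha_expected_fp=alpha_expected_fp,
                              m_tests=int(m_tests), threshold=thr,
                              rejected_de=rej_de, rejected_dc=rej_dc)


def two_group_design(labels) -> tuple[DesignMatrix, np.ndarray]:
    """Block indicator design [1 0; 0 1] and contrast C' = [1, -1]/sqrt(2).

    Groups are taken in order of first appearance in ``labels``.
    """
    labels = [str(x) for x in labels]
    groups = list(dict.fromkeys(labels))
    if len(groups) != 2:
        raise ValueError(f"need exactly two group labels, got {groups}")
    ind = np.array([[1.0, 0.0] if l == groups[0] else [0.0, 1.0]
                    for l in labels])
    D = DesignMatrix(ind, column_labels=groups)
    C = np.array([[1.0], [-1.0]]) / np.sqrt(2.0)
    return D, C


def two_group_test(X, labels, K, q: int, seed) -> TestResult:
    """Treatment-vs-control convenience wrapper.

    Identical to the general contrast path with the block design and
    C' = [1, -1]/sqrt(2); in this balanced-null-block case the residual
    permutation reduces to permuting the rows of X.
    """
    D, C = two_group_design(labels)
    return permutation_null(X, D.values, C, K, q, seed)
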