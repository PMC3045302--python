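"""Maximum-likelihood fitting of a sparse inverse covariance matrix.

Given a zero pattern N and the sample covariance S = R'R/n, the profile
log-likelihood is L = (n/2){log det K - trace(K S)} with K = Sigma^{-1}
constrained to the support of N.  Setting its derivative to zero gives the
covariance-selection likelihood equations: at the MLE the fitted covariance
matches S entrywise on the support (edges and diagonal) while the precision
is exactly zero off-support.

The fit is computed by clique-wise Iterative Proportional Scaling (IPS),
the classical fixpoint for these equations: cycling over the maximal
cliques c of the pattern graph, update

    K[c, c] += inv(S[c, c]) - inv((K^{-1})[c, c])

which matches the fitted marginal covariance on clique c exactly while
leaving all other entries of K untouched.  Each update is an exact
likelihood maximisation over the clique block, so the log-likelihood is
non-decreasing and the iterates stay positive definite whenever the MLE
exists (all clique submatrices of S positive definite).  Structural zeros
are respected by construction: updates only ever touch clique blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .pattern import ZeroPattern

__all__ = [
    "SparsePrecision",
    "FitReport",
    "ConditionalRegressions",
    "MLEDoesNotExistError",
    "mle_exists",
    "fit_precision",
    "conditional_regressions",
    "regression_approx_precision",
    "log_likelihood",
]

_PD_TOL = 1e-10


class MLEDoesNotExistError(ValueError):
    """Some clique submatrix of S is not positive definite."""


@dataclass
class SparsePrecision:
    """Sigma^{-1} with values on the support of a zero pattern."""

    K: sp.csr_matrix
    pattern: ZeroPattern | None = None

    def __post_init__(self):
        K = sp.csr_matrix(self.K, dtype=float)
        if K.shape[0] != K.shape[1]:
            raise ValueError("precision matrix must be square")
        asym = abs(K - K.T).max() if K.nnz else 0.0
        scale = max(abs(K).max(), 1.0) if K.nnz else 1.0
        if asym > 1e-8 * scale:
            raise ValueError(f"precision matrix not symmetric (max gap {asym:g})")
        K = ((K + K.T) * 0.5).tocsr()
        if self.pattern is None:
            self.pattern = ZeroPattern(K != 0)
        self.K = K

    @property
    def p(self) -> int:
        return self.K.shape[0]

    def dense(self) -> np.ndarray:
        return self.K.toarray()

    def covariance_dense(self) -> np.ndarray:
        """Sigma = K^{-1}; only for moderate p."""
        return np.linalg.inv(self.dense())


@dataclass
class FitReport:
    loglik: float
    max_edge_gap: float
    iterations: int
    converged: bool


@dataclass
class ConditionalRegressions:
    """Per-gene conditional regressions implied by a precision matrix.

    beta[i, j] = -K_ij / K_ii is the coefficient of gene j in the
    conditional regression of gene i on its neighbours; resid_var[i] =
    1 / K_ii is the conditional (residual) variance.
    """

    beta: sp.csr_matrix
    resid_var: np.ndarray


def _as_sample_cov(S, p: int | None = None):
    """Accept a dense array or a SampleCov; return an object with .block()."""
    if hasattr(S, "block"):
        return S
    S = np.asarray(S, dtype=float)

    class _Dense:
        def __init__(self, M):
            self.M = M
            self.p = M.shape[0]

        def block(self, rows, cols=None):
            rows = np.asarray(rows, dtype=int)
            cols = rows if cols is None else np.asarray(cols, dtype=int)
            return self.M[np.ix_(rows, cols)]

        def diagonal(self):
            return np.diag(self.M).copy()

        def dense(self):
            return self.M

    return _Dense(S)


def _pattern_cliques(pattern: ZeroPattern) -> list[np.ndarray]:
    from .graphs import GeneGraph, maximal_cliques

    G = GeneGraph.from_pattern(pattern)
    cliques, _ = maximal_cliques(G)
    return [np.asarray(sorted(G.index_of(g) for g in c), dtype=int)
            for c in cliques]


def mle_exists(S, cliques) -> bool:
    """MLE exists iff every clique submatrix of S is positive definite."""
    Sc = _as_sample_cov(S)
    for c in cliques:
        idx = np.asarray(sorted(c), dtype=int)
        block = Sc.block(idx)
        if np.linalg.eigvalsh(block).min() <= _PD_TOL * max(block.diagonal().max(), 1.0):
            return False
    return True


def log_likelihood(K, S, n: int) -> float:
    """L = (n/2){log det K - trace(K S)}; the trace uses only support entries."""
    if isinstance(K, SparsePrecision):
        Kc = K.K
    else:
        Kc = sp.csr_matrix(K, dtype=float)
    Sc = _as_sample_cov(S)
    coo = Kc.tocoo()
    tr = 0.0
    for i, j, v in zip(coo.row, coo.col, coo.data):
        tr += v * float(Sc.block([i], [j])[0, 0])
    p = Kc.shape[0]
    if p <= 800:
        sign, logdet = np.linalg.slogdet(Kc.toarray())
        if sign <= 0:
            raise ValueError("precision matrix is not positive definite")
    else:
        from .sparsechol import sparse_cholesky_logdet
        logdet = sparse_cholesky_logdet(Kc)
    return 0.5 * n * (logdet - tr)


def _edge_gap(Sigma_supp: dict, S_blocks: dict, corr_scale: np.ndarray) -> float:
    gap = 0.0
    for (i, j), sig in Sigma_supp.items():
        gap = max(gap, abs(sig - S_blocks[(i, j)]) / corr_scale[i] / corr_scale[j])
    return gap


def fit_precision(S, pattern: ZeroPattern, tol: float = 1e-6,
                  max_iter: int = 200, *, cliques=None, n: int | None = None,
                  ) -> tuple[SparsePrecision, FitReport]:
    """MLE of Sigma^{-1} on the support of ``pattern`` by clique-wise IPS.

    Converged when max_ij |Sigma_hat_ij - s_ij| <= tol on the support,
    measured on the correlation scale (divided by sqrt(s_ii s_jj)).  The
    off-support entries of the returned precision are exactly zero.  The
    reported log-likelihood uses ``n`` if given (else n = 1 scale).
    """
    p = pattern.p
    Sc = _as_sample_cov(S)
    if cliques is None:
        cliques = _pattern_cliques(pattern)
    cliques = [np.asarray(sorted(c), dtype=int) for c in cliques]
    if not mle_exists(Sc, cliques):
        raise MLEDoesNotExistError(
            "a clique submatrix of S is singular; reduce the pattern (smaller "
            "kmax) or provide more samples"
        )
    s_diag = Sc.diagonal()
    if (s_diag <= 0).any():
        raise MLEDoesNotExistError("zero-variance gene in S")
    corr = np.sqrt(s_diag)

    supp = pattern.offdiag_upper()
    supp_pairs = list(zip(supp.row.tolist(), supp.col.tolist()))
    S_on = {(i, j): float(Sc.block([i], [j])[0, 0]) for i, j in supp_pairs}
    for i in range(p):
        S_on[(i, i)] = float(s_diag[i])
    S_cl = {t: Sc.block(c) for t, c in enumerate(cliques)}
    S_cl_inv = {t: np.linalg.inv(Scc) for t, Scc in S_cl.items()}

    K = np.zeros((p, p))
    np.fill_diagonal(K, 1.0 / s_diag)

    nll = n if n is not None else 1

    def current_sigma_support(Kmat):
        Sigma = np.linalg.inv(Kmat)
        out = {t: Sigma[np.ix_(c, c)] for t, c in enumerate(cliques)}
        vals = {pair: Sigma[pair] for pair in supp_pairs}
        for i in range(p):
            vals[(i, i)] = Sigma[i, i]
        return out, vals

    gap = np.inf
    loglik_prev = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        for t, c in enumerate(cliques):
            E = np.zeros((p, len(c)))
            E[c, np.arange(len(c))] = 1.0
            Sigma_cc = np.linalg.solve(K, E)[c]
            Sigma_cc = (Sigma_cc + Sigma_cc.T) * 0.5
            delta = S_cl_inv[t] - np.linalg.inv(Sigma_cc)
            # exact clique update keeps K PD when the MLE exists; a step-halving
            # safeguard covers pathological rounding
            step = 1.0
            for _ in range(30):
                Knew = K.copy()
                Knew[np.ix_(c, c)] += step * delta
                try:
                    np.linalg.cholesky(Knew)
                    K = Knew
                    break
                except np.linalg.LinAlgError:
                    step *= 0.5
        _, sig_vals = current_sigma_support(K)
        gap = _edge_gap(sig_vals, S_on, corr)
        if gap <= tol:
            break
    sign, logdet = np.linalg.slogdet(K)
    # trace(K S) over the support: diagonal once, each off-diagonal pair twice
    tr = sum(K[i, i] * S_on[(i, i)] for i in range(p))
    tr += 2.0 * sum(K[i, j] * S_on[(i, j)] for (i, j) in supp_pairs)
    loglik = 0.5 * nll * (logdet - tr)

    mask = pattern.N.toarray().astype(bool)
    K = np.where(mask, K, 0.0)
    Ks = sp.csr_matrix(K)
    report = FitReport(loglik=float(loglik), max_edge_gap=float(gap),
                       iterations=it, converged=bool(gap <= tol))
    return SparsePrecision(Ks, pattern=pattern), report


def conditional_regressions(K) -> ConditionalRegressions:
    """beta_ij = -K_ij/K_ii and residual variances 1/K_ii from a precision."""
    if isinstance(K, SparsePrecision):
        Kc = K.K
    else:
        Kc = sp.csr_matrix(K, dtype=float)
    d = Kc.diagonal()
    if (d <= 0).any():
        raise ValueError("precision diagonal must be positive")
    coo = Kc.tocoo()
    off = coo.row != coo.col
    beta = sp.csr_matrix(
        (-coo.data[off] / d[coo.row[off]], (coo.row[off], coo.col[off])),
        shape=Kc.shape,
    )
    return ConditionalRegressions(beta=beta, resid_var=1.0 / d)


@dataclass
class RegressionApproxResult:
    """Regression-only approximation of Sigma^{-1} (not exact MLE).

    Each gene is regressed by OLS on its pattern neighbours; entries are
    assembled from K_ii = 1/v_i^2 and K_ij = -beta_ij * K_ii, then
    symmetrised by averaging.  The raw assembly need not be symmetric nor
    positive definite; ``asymmetry`` and ``min_eigenvalue`` report how far
    off it is.
    """

    K: sp.csr_matrix
    asymmetry: float
    min_eigenvalue: float
    is_pd: bool


def regression_approx_precision(data, pattern: ZeroPattern,
                                ) -> RegressionApproxResult:
    data = np.asarray(data, dtype=float)
    n, p = data.shape
    if pattern.p != p:
        raise ValueError("pattern dimension does not match data")
    Xc = data - data.mean(axis=0)
    N = pattern.N
    K = np.zeros((p, p))
    for i in range(p):
        nbrs = np.setdiff1d(N[i].indices, [i])
        if nbrs.size >= n:
            raise ValueError(
                f"gene {i} has {nbrs.size} neighbours but only {n} samples"
            )
        y = Xc[:, i]
        if nbrs.size == 0:
            v2 = float(y @ y) / n
            K[i, i] = 1.0 / v2
            continue
        Z = Xc[:, nbrs]
        beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
        resid = y - Z @ beta
        v2 = float(resid @ resid) / n
        K[i, i] = 1.0 / v2
        K[i, nbrs] = -beta / v2
    asym = float(np.abs(K - K.T).max())
    Ksym = (K + K.T) * 0.5
    eig_min = float(np.linalg.eigvalsh(Ksym).min())
    return RegressionApproxResult(
        K=sp.csr_matrix(Ksym), asymmetry=asym, min_eigenvalue=eig_min,
        is_pd=bool(eig_min > 0),
    )
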