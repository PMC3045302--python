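"""Zero-pattern search for the inverse covariance matrix.

The support of Sigma^{-1} is estimated gene by gene: the conditional
regression view of a Gaussian graphical model says gene i's neighbours are
exactly the genes with non-zero coefficients when i is regressed on all the
rest.  For each gene we therefore run greedy forward stepwise selection up
to a cap ``kmax``, score the path with a modified BIC whose extra
``2*gamma*log C(p, k)`` term controls false selections when p >> n, pick the
minimising model size, and collect the chosen predictors in a neighbour
matrix A.  Symmetrising, N = A + A' with unit diagonal, gives the estimated
zero pattern: (i, j) may be non-zero in Sigma^{-1} iff N_ij = 1.

The stepwise engine works on the correlation (Gram) scale.  For moderate p
the p x p Gram matrix is precomputed once; for large p the few Gram rows a
path needs are formed on demand from the data, so the dense p x p object is
never built.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.special import gammaln

__all__ = [
    "StepwisePath",
    "NeighbourMatrix",
    "ZeroPattern",
    "forward_stepwise",
    "bic_gamma",
    "bic_2p",
    "get_criterion",
    "select_size",
    "find_pattern",
    "find_pattern_multi",
    "KMAX_SAMPLE_RATIO",
]

# tentative upper limit on kmax/n (about 20 observations per parameter in
# the largest regression); above it we warn, never fail
KMAX_SAMPLE_RATIO = 1.0 / 20.0

_VAR_TOL = 1e-12


@dataclass
class StepwisePath:
    """One gene's greedy forward-selection path.

    ``resid_var[k]`` is the maximum-likelihood residual variance (RSS/n) of
    the size-k model, non-increasing in k.  ``selected`` holds predictor
    indices in the order they entered.
    """

    target_gene: int
    selected: list[int]
    resid_var: np.ndarray
    n: int
    p_choices: int

    def __post_init__(self):
        self.resid_var = np.asarray(self.resid_var, dtype=float)
        if len(self.resid_var) != len(self.selected) + 1:
            raise ValueError("resid_var must have one entry per model size 0..k")


@dataclass
class ZeroPattern:
    """Symmetric binary support N of Sigma^{-1}, unit diagonal."""

    N: sp.csr_matrix

    def __post_init__(self):
        N = sp.csr_matrix(self.N, dtype=np.int8)
        N.data[:] = 1
        N = N.maximum(N.T)
        N.setdiag(1)
        N.eliminate_zeros()
        self.N = N.tocsr()

    @property
    def p(self) -> int:
        return self.N.shape[0]

    @property
    def neighbour_sizes(self) -> np.ndarray:
        """Off-diagonal support count per gene."""
        return np.asarray((self.N != 0).sum(axis=1)).ravel() - 1

    def offdiag_upper(self) -> sp.coo_matrix:
        return sp.triu(self.N, k=1).tocoo()


@dataclass
class NeighbourMatrix:
    """A_ij = 1 iff gene j was chosen as a predictor of gene i."""

    A: sp.csr_matrix

    def __post_init__(self):
        A = sp.csr_matrix(self.A, dtype=np.int8)
        if A.diagonal().any():
            raise ValueError("neighbour matrix must have zero diagonal")
        self.A = A

    def symmetrize(self) -> ZeroPattern:
        return ZeroPattern(self.A)


# --------------------------------------------------------------------------
# model-size criteria

def _log_binomial(p_choices: int, k: int) -> float:
    """log C(p, k) via log-gamma; safe for p in the tens of thousands."""
    if k < 0 or k > p_choices:
        raise ValueError(f"k={k} outside 0..{p_choices}")
    return float(
        gammaln(p_choices + 1) - gammaln(k + 1) - gammaln(p_choices - k + 1)
    )


def bic_gamma(n: int, k: int, p_choices: int, resid_var_k: float,
              gamma: float = 1.0) -> float:
    """Modified BIC: n log s2(k) + k log n + 2*gamma*log C(p, k).

    gamma = 0 is the usual BIC; gamma = 1 is the recommended choice when
    p >> n.  A perfect fit (s2 = 0) scores -inf: it cannot be beaten.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    if resid_var_k < 0:
        raise ValueError("residual variance must be non-negative")
    if resid_var_k == 0.0:
        return -math.inf
    return (n * math.log(resid_var_k) + k * math.log(n)
            + 2.0 * gamma * _log_binomial(p_choices, k))


def bic_2p(n: int, k: int, p_choices: int, resid_var_k: float) -> float:
    """Alternative modified BIC: n log s2(k) + 2 k log p."""
    if resid_var_k < 0:
        raise ValueError("residual variance must be non-negative")
    if resid_var_k == 0.0:
        return -math.inf
    return n * math.log(resid_var_k) + 2.0 * k * math.log(p_choices)


def get_criterion(name) -> Callable[[int, int, int, float], float]:
    """Resolve a criterion spec ('bic1.0', 'bic0.5', 'bic0.0', 'bic2p' or a
    callable (n, k, p_choices, resid_var) -> score) to a callable."""
    if callable(name):
        return name
    name = str(name).lower()
    if name == "bic2p":
        return bic_2p
    if name.startswith("bic"):
        g = float(name[3:])
        return lambda n, k, p, rv: bic_gamma(n, k, p, rv, gamma=g)
    raise ValueError(f"unknown criterion {name!r}")


def select_size(path: StepwisePath, criterion="bic1.0") -> int:
    """argmin_k criterion(k) along the path; ties go to the smallest k."""
    crit = get_criterion(criterion)
    scores = [crit(path.n, k, path.p_choices, path.resid_var[k])
              for k in range(len(path.resid_var))]
    return int(np.argmin(scores))


# --------------------------------------------------------------------------
# stepwise engine (correlation scale, incremental Cholesky)

def _stepwise_core(c: np.ndarray, diag: np.ndarray, gram_row, kmax: int,
                   eligible: np.ndarray, y_var: float, n: int) -> tuple[list[int], list[float]]:
    """Greedy forward selection given covariances on a common scale.

    c[j] = cov(z_j, y); diag[j] = var(z_j); gram_row(j) -> cov(z_j, z).
    Returns (selected, resid_var list of length len(selected)+1), with
    resid_var on the scale of y_var.  Maintains V = L^{-1} G[S, :] and
    w = L^{-1} c[S] so each step costs O(k p).
    """
    p = c.shape[0]
    V = np.empty((kmax, p))
    w = np.empty(kmax)
    avail = eligible.copy()
    avail &= diag > _VAR_TOL
    selected: list[int] = []
    rv = [y_var]
    if y_var <= _VAR_TOL:
        return selected, rv
    resid_cov = c.copy()
    resid_diag = diag.astype(float).copy()
    for step in range(kmax):
        ok = avail & (resid_diag > _VAR_TOL * np.maximum(diag, 1.0))
        if not ok.any():
            break
        score = np.where(ok, resid_cov**2 / np.where(ok, resid_diag, 1.0), -np.inf)
        j = int(np.argmax(score))  # ties -> lowest index
        gain = score[j]
        if gain <= 0:
            break
        new_rv = rv[-1] - gain
        d = math.sqrt(resid_diag[j])
        g = np.asarray(gram_row(j), dtype=float)
        if step:
            v_new = (g - V[:step].T @ V[:step, j]) / d
        else:
            v_new = g / d
        V[step] = v_new
        w[step] = resid_cov[j] / d
        avail[j] = False
        selected.append(j)
        rv.append(max(new_rv, 0.0))
        if rv[-1] <= _VAR_TOL * max(y_var, 1.0):
            rv[-1] = 0.0
            break
        resid_cov -= w[step] * v_new
        resid_diag -= v_new**2
    return selected, rv


def forward_stepwise(y, Z, kmax: int, *, standardize: bool = True) -> StepwisePath:
    """Forward stepwise regression of y on the columns of Z, up to kmax terms.

    At each step the predictor giving the largest residual-sum-of-squares
    reduction (equivalently the largest absolute correlation with the current
    residual) enters; ties break to the lowest column index.  Columns with
    (numerically) zero variance are skipped.  Residual variances use the
    maximum-likelihood divisor n.
    """
    y = np.asarray(y, dtype=float).ravel()
    Z = np.asarray(Z, dtype=float)
    n = y.shape[0]
    if Z.shape[0] != n:
        raise ValueError("y and Z have different numbers of rows")
    if kmax < 1:
        raise ValueError("kmax must be >= 1")
    if kmax >= n:
        raise ValueError(f"kmax={kmax} would saturate the model (n={n})")
    p = Z.shape[1]
    yc = y - y.mean()
    y_var = float(yc @ yc) / n
    Zc = Z - Z.mean(axis=0)
    col_var = np.einsum("ij,ij->j", Zc, Zc) / n
    constant = col_var <= _VAR_TOL
    if constant.any():
        warnings.warn(
            f"skipping {int(constant.sum())} constant predictor column(s)",
            stacklevel=2,
        )
    if standardize:
        scale = np.where(constant, 1.0, np.sqrt(col_var))
        Zc = Zc / scale
        diag = np.where(constant, 0.0, 1.0)
    else:
        diag = col_var
    c = Zc.T @ yc / n
    gram_row = lambda j: Zc.T @ Zc[:, j] / n
    selected, rv = _stepwise_core(
        c, diag, gram_row, kmax, ~constant, y_var, n
    )
    return StepwisePath(target_gene=-1, selected=selected,
                        resid_var=np.asarray(rv), n=n, p_choices=p)


class _PatternEngine:
    """Shared state for the p per-gene stepwise regressions.

    Columns are centered and (by default) standardized once.  If p is small
    enough the correlation Gram matrix is precomputed, making each per-gene
    path independent of n; otherwise Gram rows are formed on demand.
    """

    def __init__(self, data: np.ndarray, kmax: int, *, standardize: bool = True,
                 gram_limit: int = 3000):
        data = np.asarray(data, dtype=float)
        n, p = data.shape
        if p < 2:
            raise ValueError("need at least 2 genes")
        if kmax >= n:
            raise ValueError(f"kmax={kmax} would saturate the model (n={n})")
        if kmax / n > KMAX_SAMPLE_RATIO:
            warnings.warn(
                f"kmax/n = {kmax}/{n} exceeds the recommended 1/20 "
                "(fewer than 20 observations per parameter in the largest "
                "regressions)", stacklevel=3,
            )
        self.n, self.p, self.kmax = n, p, kmax
        Zc = data - data.mean(axis=0)
        col_var = np.einsum("ij,ij->j", Zc, Zc) / n
        self.constant = col_var <= _VAR_TOL
        if self.constant.any():
            warnings.warn(
                f"skipping {int(self.constant.sum())} constant gene column(s)",
                stacklevel=3,
            )
        self.col_var = col_var
        if standardize:
            scale = np.where(self.constant, 1.0, np.sqrt(col_var))
            self.Z = Zc / scale
            self.diag = np.where(self.constant, 0.0, 1.0)
        else:
            self.Z = Zc
            self.diag = col_var
        self.G = (self.Z.T @ self.Z) / n if p <= gram_limit else None

    def gram_row(self, j: int) -> np.ndarray:
        if self.G is not None:
            return self.G[j]
        return self.Z.T @ self.Z[:, j] / self.n

    def path(self, i: int) -> StepwisePath:
        eligible = ~self.constant
        eligible = eligible.copy()
        eligible[i] = False
        y_var = self.diag[i] if not self.constant[i] else 0.0
        selected, rv = _stepwise_core(
            self.gram_row(i).copy(), self.diag, self.gram_row, self.kmax,
            eligible, float(y_var), self.n,
        )
        # report residual variance on the original scale of gene i
        rv = np.asarray(rv) * (self.col_var[i] / y_var if y_var > 0 else 1.0)
        return StepwisePath(target_gene=i, selected=selected, resid_var=rv,
                            n=self.n, p_choices=self.p - 1)


def default_kmax(n: int) -> int:
    """floor(n/20), at least 1 — about 20 observations per parameter."""
    return max(1, n // 20)


def find_pattern_multi(data, kmax: int | None = None,
                       criteria: Sequence = ("bic1.0",), *,
                       standardize: bool = True, n_jobs: int = 1,
                       ) -> dict[str, tuple[NeighbourMatrix, ZeroPattern]]:
    """Run the p stepwise paths once; select sizes under several criteria.

    The greedy path does not depend on the criterion, so evaluating multiple
    BIC variants on the same data costs almost nothing extra.  Results are
    deterministic given (data, kmax, criteria) regardless of n_jobs.
    """
    data = np.asarray(data, dtype=float)
    n, p = data.shape
    if kmax is None:
        kmax = default_kmax(n)
    eng = _PatternEngine(data, kmax, standardize=standardize)

    if n_jobs != 1:
        from joblib import Parallel, delayed
        chunks = np.array_split(np.arange(p), max(n_jobs * 4, 1))
        results = Parallel(n_jobs=n_jobs, prefer="threads")(
            delayed(lambda idx: [eng.path(i) for i in idx])(ch)
            for ch in chunks if len(ch)
        )
        paths = [pth for chunk in results for pth in chunk]
    else:
        paths = [eng.path(i) for i in range(p)]

    out: dict[str, tuple[NeighbourMatrix, ZeroPattern]] = {}
    for criterion in criteria:
        key = criterion if isinstance(criterion, str) else getattr(
            criterion, "__name__", str(criterion))
        rows, cols = [], []
        for pth in paths:
            ksel = select_size(pth, criterion)
            for j in pth.selected[:ksel]:
                # candidate index -> gene index (self was excluded by mask,
                # indices are already gene indices)
                rows.append(pth.target_gene)
                cols.append(j)
        A = sp.csr_matrix(
            (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(p, p)
        )
        nb = NeighbourMatrix(A)
        out[key] = (nb, nb.symmetrize())
    return out


def find_pattern(data, kmax: int | None = None, criterion="bic1.0", *,
                 standardize: bool = True, n_jobs: int = 1,
                 ) -> tuple[NeighbourMatrix, ZeroPattern]:
    """Estimate the zero pattern of Sigma^{-1} from data (n x p).

    Pass residuals (after removing the design mean structure) for model-based
    use; raw columns also work since each path centers its variables.
    """
    res = find_pattern_multi(data, kmax, [criterion], standardize=standardize,
                             n_jobs=n_jobs)
    return next(iter(res.values()))
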