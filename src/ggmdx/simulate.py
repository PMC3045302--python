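"""Synthetic sparse precision matrices and multivariate-normal expression data.

The generator follows a three-step recipe that controls sparsity, effect
magnitude and positive definiteness simultaneously:

1. Build a random neighbour matrix A by selecting about ``q`` entries in
   each row; symmetrise to N = A + A' with unit diagonal.  Neighbour sizes
   then vary around 2q (row picks plus incoming column picks), and q tunes
   the median neighbour size m.
2. Give every off-diagonal support entry a value drawn away from zero —
   by default a magnitude uniform on [0.5, 1] with random sign — and
   symmetrise.
3. Set each diagonal to d times the row's absolute off-diagonal sum, with
   the multiplier d stepped down from 1 in steps of 0.05 until positive
   definiteness would be lost; the smallest PD value is kept.  Shrinking d
   below exact diagonal dominance is what gives the data a usable signal
   to noise ratio.

Sampling from N(0, K^{-1}) and the pattern-recovery bookkeeping
(confusion matrices over unordered gene pairs) complete the simulation
study machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .pattern import ZeroPattern, default_kmax, find_pattern_multi
from .precision import SparsePrecision
from .sparsechol import is_positive_definite, sample_gaussian_from_precision

__all__ = [
    "SimConfig",
    "GeneratedModel",
    "ConfusionMatrix",
    "generate_neighbour_pattern",
    "calibrate_q",
    "generate_precision",
    "sample_mvn",
    "evaluate_pattern",
    "run_study",
    "StudyResult",
]


@dataclass
class SimConfig:
    """Settings for one cell of the simulation study.

    ``q_per_row`` may be fractional: each row draws floor(q) or ceil(q)
    entries so that the average is q, which is what lets the median
    neighbour size hit odd targets like 5.  If ``q_per_row`` is None it is
    calibrated from ``target_median``.
    """

    p: int
    n: int
    q_per_row: float | None = None
    target_median: int | None = None
    value_low: float = 0.5
    value_high: float = 1.0
    value_interval: str = "symmetric"   # or "printed": [-1, 0.5] u [0.5, 1]
    d_step: float = 0.05
    reps: int = 10
    seed: int | None = None
    kmax: int | None = None

    def __post_init__(self):
        if self.q_per_row is None and self.target_median is None:
            raise ValueError("give q_per_row or target_median")
        if self.q_per_row is not None and self.q_per_row < 1:
            raise ValueError("q_per_row must be >= 1")
        if not 0 < self.d_step < 1:
            raise ValueError("d_step must lie in (0, 1)")


@dataclass
class GeneratedModel:
    K_true: SparsePrecision
    N_true: ZeroPattern
    d_used: float
    q_used: float
    neighbour_size_stats: dict = field(default_factory=dict)


@dataclass
class ConfusionMatrix:
    """Edge-recovery counts over unordered off-diagonal gene pairs."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total_pairs(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def fp_rate(self) -> float:
        return self.fp / (self.fp + self.tn) if (self.fp + self.tn) else 0.0

    @property
    def fn_rate(self) -> float:
        return self.fn / (self.fn + self.tp) if (self.fn + self.tp) else 0.0


def _row_counts(rng: np.random.Generator, p: int, q: float) -> np.ndarray:
    base = int(np.floor(q))
    frac = q - base
    counts = np.full(p, base)
    if frac > 0:
        counts += rng.random(p) < frac
    return np.minimum(counts, p - 1)


def generate_neighbour_pattern(p: int, q: float, rng: np.random.Generator,
                               ) -> ZeroPattern:
    """Step 1 only: random row-wise selections, symmetrised."""
    counts = _row_counts(rng, p, q)
    rows, cols = [], []
    for i in range(p):
        k = counts[i]
        if k == 0:
            continue
        picks = rng.choice(p - 1, size=k, replace=False)
        picks = picks + (picks >= i)          # skip the diagonal
        rows.extend([i] * k)
        cols.extend(picks.tolist())
    A = sp.csr_matrix((np.ones(len(rows), np.int8), (rows, cols)), shape=(p, p))
    return ZeroPattern(A)


def calibrate_q(p: int, target_median: int, seed, *, reps: int = 2,
                ) -> float:
    """Pilot search for the q giving median neighbour size ~ target.

    Only step 1 is needed (the median depends on the pattern alone), so the
    search is cheap even at large p.  Grid in steps of 0.25; ties go to the
    smaller q.
    """
    rng = np.random.default_rng(seed)
    qs = np.arange(max(1.0, target_median / 2 - 1.5),
                   target_median / 2 + 1.75, 0.25)
    best, best_err = qs[0], np.inf
    for q in qs:
        meds = []
        for _ in range(reps):
            N = generate_neighbour_pattern(p, float(q), rng)
            meds.append(np.median(N.neighbour_sizes))
        err = abs(float(np.mean(meds)) - target_median)
        if err < best_err - 1e-12:
            best, best_err = q, err
    return float(best)


def generate_precision(config: SimConfig, seed=None) -> GeneratedModel:
    """Steps 1-3: pattern, off-diagonal values, diagonal scaling d.

    The d search steps down from 1 by ``d_step``; d = 1 (diagonal equal to
    the absolute row sum) is diagonally dominant and in practice always PD
    for these random sign patterns, so the search terminates.  PD is tested
    by sparse Cholesky success.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    p = config.p
    q = config.q_per_row
    if q is None:
        q = calibrate_q(p, config.target_median, rng.integers(2**31 - 1))
    N = generate_neighbour_pattern(p, q, rng)
    upper = N.offdiag_upper()
    m = upper.nnz
    if config.value_interval == "symmetric":
        vals = rng.uniform(config.value_low, config.value_high, size=m)
        vals *= rng.choice([-1.0, 1.0], size=m)
    elif config.value_interval == "printed":
        # literal union [-1, 0.5] u [0.5, 1], pieces weighted by length
        left = rng.random(m) < 1.5 / 2.0
        vals = np.where(left, rng.uniform(-1.0, 0.5, size=m),
                        rng.uniform(0.5, 1.0, size=m))
    else:
        raise ValueError(f"unknown value_interval {config.value_interval!r}")
    Koff = sp.coo_matrix((vals, (upper.row, upper.col)), shape=(p, p)).tocsr()
    Koff = Koff + Koff.T
    rowsum = np.asarray(abs(Koff).sum(axis=1)).ravel()
    if (rowsum <= 0).any():
        # a gene with no neighbours would get a zero diagonal; give it unit
        # precision (independent gene) instead
        rowsum = np.where(rowsum <= 0, 1.0, rowsum)

    def K_of(d):
        K = Koff.copy().tolil()
        K.setdiag(d * rowsum)
        return K.tocsc()

    d = 1.0
    if not is_positive_definite(K_of(d)):
        raise RuntimeError("matrix not PD even at d = 1")
    while d - config.d_step > 0:
        cand = round(d - config.d_step, 10)
        if is_positive_definite(K_of(cand)):
            d = cand
        else:
            break
    K = sp.csr_matrix(K_of(d))
    sizes = N.neighbour_sizes
    stats = {
        "median": float(np.median(sizes)),
        "q05": float(np.quantile(sizes, 0.05)),
        "q95": float(np.quantile(sizes, 0.95)),
        "max": int(sizes.max()),
        "frac_3_8": float(np.mean((sizes >= 3) & (sizes <= 8))),
        "frac_8_15": float(np.mean((sizes >= 8) & (sizes <= 15))),
    }
    return GeneratedModel(
        K_true=SparsePrecision(K, pattern=N), N_true=N, d_used=float(d),
        q_used=float(q), neighbour_size_stats=stats,
    )


def sample_mvn(K, n: int, seed) -> np.ndarray:
    """n i.i.d. rows from N(0, K^{-1}), via one sparse triangular solve."""
    Kc = K.K if isinstance(K, SparsePrecision) else sp.csc_matrix(K)
    rng = np.random.default_rng(seed)
    return sample_gaussian_from_precision(Kc, n, rng)


def evaluate_pattern(N_hat: ZeroPattern, N_true: ZeroPattern) -> ConfusionMatrix:
    """Confusion counts over the p(p-1)/2 unordered off-diagonal pairs."""
    if N_hat.p != N_true.p:
        raise ValueError("patterns have different dimensions")
    p = N_hat.p
    pred = sp.triu(N_hat.N, k=1).astype(bool)
    true = sp.triu(N_true.N, k=1).astype(bool)
    tp = int(pred.multiply(true).nnz)
    fp = int(pred.nnz - tp)
    fn = int(true.nnz - tp)
    total = p * (p - 1) // 2
    tn = total - tp - fp - fn
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


@dataclass
class StudyResult:
    """Per-criterion recovery results across repetitions."""

    config: SimConfig
    criteria: list[str]
    confusions: dict[str, list[ConfusionMatrix]]
    models: list[GeneratedModel] = field(repr=False, default_factory=list)

    def summary(self) -> pd.DataFrame:
        rows = []
        for crit in self.criteria:
            cms = self.confusions[crit]
            arr = np.array([[c.tp, c.fp, c.fn, c.tn] for c in cms], float)
            mean = arr.mean(0)
            sd = arr.std(0, ddof=1) if len(cms) > 1 else np.zeros(4)
            rows.append({
                "criterion": crit,
                "tp_mean": mean[0], "tp_sd": sd[0],
                "fp_mean": mean[1], "fp_sd": sd[1],
                "fn_mean": mean[2], "fn_sd": sd[2],
                "tn_mean": mean[3], "tn_sd": sd[3],
                "fp_rate": float(np.mean([c.fp_rate for c in cms])),
                "fn_rate": float(np.mean([c.fn_rate for c in cms])),
            })
        return pd.DataFrame(rows)


def run_study(config: SimConfig, criteria=("bic0.0", "bic0.5", "bic1.0", "bic2p"),
              *, n_jobs: int = 1) -> StudyResult:
    """Generate -> sample -> find pattern -> score, repeated ``reps`` times.

    The stepwise paths are computed once per data set and scored under all
    requested criteria, since the greedy path does not depend on the
    criterion.  Deterministic for a fixed config seed.
    """
    criteria = [c if isinstance(c, str) else str(c) for c in criteria]
    ss = np.random.SeedSequence(config.seed)
    kmax = config.kmax if config.kmax is not None else default_kmax(config.n)
    confusions: dict[str, list[ConfusionMatrix]] = {c: [] for c in criteria}
    models: list[GeneratedModel] = []
    for rep_seed in ss.spawn(config.reps):
        child = np.random.default_rng(rep_seed)
        model = generate_precision(config, seed=child.integers(2**31 - 1))
        data = sample_mvn(model.K_true, config.n, child.integers(2**31 - 1))
        patterns = find_pattern_multi(data, kmax, criteria, n_jobs=n_jobs)
        for crit in criteria:
            _, N_hat = patterns[crit]
            confusions[crit].append(evaluate_pattern(N_hat, model.N_true))
        models.append(model)
    return StudyResult(config=config, criteria=criteria,
                       confusions=confusions, models=models)
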