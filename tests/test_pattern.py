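"""Forward stepwise selection, modified BIC and zero-pattern search."""

import math

import numpy as np
import pytest
from numpy.testing import assert_allclose

from ggmdx import (
    SimConfig,
    ZeroPattern,
    bic_2p,
    bic_gamma,
    find_pattern,
    find_pattern_multi,
    forward_stepwise,
    generate_precision,
    sample_mvn,
    select_size,
)
from ggmdx.pattern import StepwisePath, default_kmax


def greedy_oracle(y, Z, kmax):
    """Brute-force greedy: at each step refit OLS with every remaining
    candidate added and keep the one with smallest RSS."""
    n = len(y)
    yc = y - y.mean()
    Zc = Z - Z.mean(axis=0)
    selected = []
    rvs = [float(yc @ yc) / n]
    for _ in range(kmax):
        best = None
        for j in range(Z.shape[1]):
            if j in selected:
                continue
            cols = Zc[:, selected + [j]]
            beta, *_ = np.linalg.lstsq(cols, yc, rcond=None)
            rss = float(((yc - cols @ beta) ** 2).sum())
            if best is None or rss < best[1] - 1e-12:
                best = (j, rss)
        selected.append(best[0])
        rvs.append(best[1] / n)
    return selected, rvs


class TestForwardStepwise:
    def test_exact_predictor_found_first(self, rng):
        Z = rng.standard_normal((30, 6))
        y = Z[:, 3].copy()
        path = forward_stepwise(y, Z, kmax=3)
        assert path.selected[0] == 3
        assert path.resid_var[1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_exhaustive_greedy_oracle(self, rng):
        for _ in range(5):
            n, p = 40, 12
            Z = rng.standard_normal((n, p))
            y = Z[:, :3] @ np.array([1.0, -2.0, 0.5]) + rng.standard_normal(n)
            path = forward_stepwise(y, Z, kmax=5, standardize=False)
            sel, rvs = greedy_oracle(y, Z, 5)
            assert path.selected == sel
            assert_allclose(path.resid_var, rvs, rtol=1e-8)

    def test_resid_var_monotone_non_increasing(self, rng):
        Z = rng.standard_normal((50, 20))
        y = rng.standard_normal(50)
        path = forward_stepwise(y, Z, kmax=10)
        assert (np.diff(path.resid_var) <= 1e-12).all()

    def test_five_gene_network_neighbours_stabilize(self, five_gene_pattern, rng):
        """In the 5-variable example network, the conditional regression of
        gene 1 on the rest has support {2, 4}; at large n the first two
        stepwise picks for gene 1 are exactly those neighbours."""
        import scipy.sparse as sp

        vals = {(0, 1): 0.6, (0, 3): -0.7, (1, 2): 0.5, (1, 4): 0.6,
                (2, 3): -0.5, (2, 4): 0.7, (3, 4): 0.5}
        K = np.zeros((5, 5))
        for (i, j), v in vals.items():
            K[i, j] = K[j, i] = v
        np.fill_diagonal(K, np.abs(K).sum(axis=1) * 0.9)
        assert np.linalg.eigvalsh(K).min() > 0
        X = sample_mvn(sp.csc_matrix(K), 4000, seed=7)
        path = forward_stepwise(X[:, 0], X, kmax=2)
        # column 0 is the response itself; engine never self-selects here
        # because we pass Z without the response
        path = forward_stepwise(X[:, 0], X[:, 1:], kmax=2)
        picked = {j + 1 for j in path.selected}
        assert picked == {1, 3}

    def test_kmax_saturation_rejected(self, rng):
        with pytest.raises(ValueError, match="saturate"):
            forward_stepwise(rng.standard_normal(5), rng.standard_normal((5, 8)),
                             kmax=5)

    def test_constant_columns_skipped_with_warning(self, rng):
        Z = rng.standard_normal((20, 4))
        Z[:, 1] = 2.0
        y = Z[:, 0] + 0.1 * rng.standard_normal(20)
        with pytest.warns(UserWarning, match="constant"):
            path = forward_stepwise(y, Z, kmax=2)
        assert 1 not in path.selected


class TestBICCriteria:
    def test_k0_reduces_to_fit_term(self):
        for gamma in (0.0, 0.5, 1.0):
            assert bic_gamma(50, 0, 400, 2.0, gamma) == pytest.approx(
                50 * math.log(2.0))
        assert bic_2p(50, 0, 400, 2.0) == pytest.approx(50 * math.log(2.0))

    def test_gamma_zero_is_plain_bic(self):
        n, k, p, rv = 120, 4, 800, 0.7
        assert bic_gamma(n, k, p, rv, 0.0) == pytest.approx(
            n * math.log(rv) + k * math.log(n))

    def test_log_binomial_against_exact_integer_oracle(self):
        n, k, p, rv, gamma = 100, 3, 1000, 0.5, 1.0
        exact = n * math.log(rv) + k * math.log(n) + 2 * gamma * math.log(
            math.comb(p, k))
        assert bic_gamma(n, k, p, rv, gamma) == pytest.approx(exact, rel=1e-12)
        # huge p must not overflow
        assert np.isfinite(bic_gamma(100, 10, 20000, 0.5, 1.0))

    def test_bic2p_hand_computation_and_algebra(self):
        n, k, p, rv = 100, 3, 1000, 0.5
        assert bic_2p(n, k, p, rv) == pytest.approx(
            n * math.log(0.5) + 6 * math.log(1000))
        # BIC2p = BIC_{gamma=0} + (2 log p - log n) k
        diff = bic_2p(n, k, p, rv) - bic_gamma(n, k, p, rv, 0.0)
        assert diff == pytest.approx((2 * math.log(p) - math.log(n)) * k)

    def test_perfect_fit_scores_minus_infinity(self):
        assert bic_gamma(50, 2, 100, 0.0, 1.0) == -math.inf
        assert bic_2p(50, 2, 100, 0.0) == -math.inf


class TestSelectSize:
    def test_monotone_increasing_criterion_selects_zero(self):
        path = StepwisePath(0, [3, 1, 2], np.array([1.0, 0.9, 0.85, 0.84]),
                            n=100, p_choices=10)
        assert select_size(path, lambda n, k, p, rv: float(k)) == 0

    def test_strong_signal_recovers_true_size(self, rng):
        n, p = 400, 10
        Z = rng.standard_normal((n, p))
        y = Z[:, :3] @ np.array([2.0, -2.0, 1.5]) + rng.standard_normal(n)
        path = forward_stepwise(y, Z, kmax=6)
        assert select_size(path, "bic1.0") == 3
        assert set(path.selected[:3]) == {0, 1, 2}

    def test_pure_noise_mostly_selects_empty_model(self, rng):
        hits = 0
        for _ in range(20):
            Z = rng.standard_normal((60, 30))
            y = rng.standard_normal(60)
            path = forward_stepwise(y, Z, kmax=3)
            hits += select_size(path, "bic1.0") == 0
        assert hits >= 17

    def test_gamma_one_never_selects_more_than_gamma_zero(self, rng):
        for _ in range(10):
            Z = rng.standard_normal((50, 25))
            y = Z[:, 0] * 0.5 + rng.standard_normal(50)
            path = forward_stepwise(y, Z, kmax=4)
            assert select_size(path, "bic1.0") <= select_size(path, "bic0.0")


class TestFindPattern:
    def test_symmetry_unit_diagonal_and_support(self, rng):
        data = rng.standard_normal((80, 15))
        A, N = find_pattern(data, kmax=3, criterion="bic0.0")
        Nd = N.N.toarray()
        assert (Nd == Nd.T).all()
        assert (np.diag(Nd) == 1).all()
        Ad = A.A.toarray()
        assert (Nd[Ad.astype(bool)] == 1).all()

    def test_independent_genes_give_near_identity(self, rng):
        data = rng.standard_normal((100, 40))
        _, N = find_pattern(data, kmax=3, criterion="bic1.0")
        false_edges = (N.N.sum() - N.p) / 2
        assert false_edges <= 3

    def test_duplicated_gene_always_selected_first(self, rng):
        data = rng.standard_normal((50, 8))
        data[:, 5] = data[:, 2]
        A, _ = find_pattern(data, kmax=2, criterion="bic0.0")
        assert A.A[2, 5] == 1 and A.A[5, 2] == 1

    def test_recovery_from_known_sparse_precision(self, rng):
        from ggmdx import evaluate_pattern

        model = generate_precision(SimConfig(p=60, n=500, q_per_row=2, seed=11))
        data = sample_mvn(model.K_true, 600, seed=12)
        _, N = find_pattern(data, kmax=8, criterion="bic1.0")
        cm = evaluate_pattern(N, model.N_true)
        assert cm.fn_rate < 0.15
        assert cm.fp_rate < 0.02

    def test_deterministic_across_worker_counts(self, rng):
        data = rng.standard_normal((60, 20))
        _, N1 = find_pattern(data, kmax=3, criterion="bic0.5", n_jobs=1)
        _, N2 = find_pattern(data, kmax=3, criterion="bic0.5", n_jobs=2)
        assert (N1.N != N2.N).nnz == 0

    def test_kmax_ratio_warning(self, rng):
        data = rng.standard_normal((40, 10))
        with pytest.warns(UserWarning, match="1/20"):
            find_pattern(data, kmax=4, criterion="bic0.0")

    def test_single_gene_rejected(self, rng):
        with pytest.raises(ValueError, match="2 genes"):
            find_pattern(rng.standard_normal((10, 1)), kmax=1)

    def test_default_kmax_follows_one_twentieth_rule(self):
        assert default_kmax(100) == 5
        assert default_kmax(500) == 25
        assert default_kmax(10) == 1

    def test_fp_edges_decrease_with_gamma_on_null_data(self, rng):
        """Under independence the false-positive edge count is ordered
        bic0.0 >= bic0.5 >= bic1.0 (heavier penalties select less)."""
        counts = {"bic0.0": 0, "bic0.5": 0, "bic1.0": 0}
        for seed in range(5):
            data = np.random.default_rng(seed).standard_normal((80, 50))
            res = find_pattern_multi(data, 3, list(counts))
            for crit in counts:
                _, N = res[crit]
                counts[crit] += int((N.N.sum() - N.p) // 2)
        assert counts["bic0.0"] >= counts["bic0.5"] >= counts["bic1.0"]


class TestZeroPattern:
    def test_construction_symmetrizes_and_sets_diagonal(self):
        import scipy.sparse as sp

        A = sp.csr_matrix(np.array([[0, 1, 0], [0, 0, 0], [0, 1, 0]]))
        N = ZeroPattern(A)
        Nd = N.N.toarray()
        assert (Nd == Nd.T).all()
        assert (np.diag(Nd) == 1).all()
        assert N.neighbour_sizes.tolist() == [1, 2, 1]
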