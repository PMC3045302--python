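"""Contrast reparameterisation, the statistic T, and permutation nulls."""

import numpy as np
import pytest
import scipy.sparse as sp
from numpy.testing import assert_allclose

from ggmdx import (
    SimConfig,
    SparsePrecision,
    build_frame,
    generate_precision,
    modified_bonferroni,
    orthogonal_complete,
    permutation_null,
    sample_mvn,
    statistic_T,
    two_group_design,
    two_group_test,
)
from conftest import random_pd_cov


def two_group_D(n1, n2):
    D = np.zeros((n1 + n2, 2))
    D[:n1, 0] = 1
    D[n1:, 1] = 1
    return D


C_TWO_GROUP = np.array([[1.0], [-1.0]]) / np.sqrt(2)


class TestOrthogonalComplete:
    def test_two_group_contrast_completion(self):
        Q = orthogonal_complete(C_TWO_GROUP)
        expected = np.array([[1, 1], [1, -1]]) / np.sqrt(2)
        assert_allclose(Q, expected, atol=1e-12)

    def test_identity_tail_gets_identity_head(self):
        C = np.eye(4)[:, 2:]
        Q = orthogonal_complete(C)
        assert_allclose(np.abs(Q[:, :2]), np.eye(4)[:, :2], atol=1e-12)
        assert_allclose(Q[:, 2:], C, atol=1e-12)

    def test_random_orthonormal_contrast_gives_orthogonal_Q(self, rng):
        for _ in range(5):
            M = rng.standard_normal((5, 2))
            C, _ = np.linalg.qr(M)
            Q = orthogonal_complete(C)
            assert_allclose(Q.T @ Q, np.eye(5), atol=1e-12)
            assert_allclose(Q[:, 3:], C, atol=1e-12)

    def test_full_rank_contrast_is_orthonormalized(self, rng):
        C = np.array([[2.0], [-2.0], [0.0]])
        Q = orthogonal_complete(C)
        assert_allclose(Q.T @ Q, np.eye(3), atol=1e-12)
        # same column space as the original contrast
        assert abs(Q[:, -1] @ C.ravel()) == pytest.approx(
            np.linalg.norm(C), rel=1e-12)

    def test_too_many_contrasts_rejected(self):
        with pytest.raises(ValueError, match="s < r"):
            orthogonal_complete(np.eye(2), r=2)


class TestBuildFrame:
    def test_two_group_reparameterized_design(self):
        n1, n2 = 3, 2
        X = np.random.default_rng(0).standard_normal((5, 4))
        frame = build_frame(X, two_group_D(n1, n2), C_TWO_GROUP)
        expect = np.vstack([
            np.column_stack([np.ones(n1), np.ones(n1)]),
            np.column_stack([np.ones(n2), -np.ones(n2)]),
        ]) / np.sqrt(2)
        assert_allclose(frame.D_tilde, expect, atol=1e-12)

    def test_balanced_two_group_G22_is_2_over_n(self, rng):
        n = 12
        X = rng.standard_normal((n, 3))
        frame = build_frame(X, two_group_D(n // 2, n // 2), C_TWO_GROUP)
        assert frame.G22[0, 0] == pytest.approx(2.0 / n)

    def test_gamma_is_rotated_coefficients(self, rng):
        """With an orthogonal design basis, Gamma_hat = Q' B_hat."""
        from ggmdx import estimate_coefficients

        n = 20
        D = np.column_stack([np.ones(n), np.repeat([1.0, -1.0], n // 2)])
        X = rng.standard_normal((n, 5))
        frame = build_frame(X, D, C_TWO_GROUP)
        B = estimate_coefficients(X, D).values
        assert_allclose(frame.Gamma_hat, frame.Q.T @ B, atol=1e-10)


class TestStatisticT:
    def test_identity_precision_reduces_to_norms(self, rng):
        X = rng.standard_normal((10, 6))
        frame = build_frame(X, two_group_D(5, 5), C_TWO_GROUP)
        K = SparsePrecision(sp.eye(6, format="csr"))
        res = statistic_T(frame, K)
        assert res.T_obs == pytest.approx((frame.Gamma2_tilde ** 2).sum())
        assert_allclose(res.gamma_nb, res.gamma, atol=1e-12)

    def test_two_group_closed_form_scalar(self, rng):
        """T equals n1 n2/(n1+n2) * d' Sigma^{-1} d with d the difference
        of group mean vectors."""
        n1, n2, p = 7, 9, 5
        X = rng.standard_normal((n1 + n2, p))
        Kd = np.linalg.inv(random_pd_cov(rng, p))
        K = SparsePrecision(sp.csr_matrix(Kd))
        frame = build_frame(X, two_group_D(n1, n2), C_TWO_GROUP)
        res = statistic_T(frame, K)
        d = X[:n1].mean(0) - X[n1:].mean(0)
        closed = n1 * n2 / (n1 + n2) * d @ Kd @ d
        assert res.T_obs == pytest.approx(closed, rel=1e-10)

    def test_trace_identity_chain(self, rng):
        """trace{(G22)^-1 G2 K G2'} = trace(G2~ K G2~') = sum of per-gene
        components, for a multi-row contrast."""
        n, r, s, p = 30, 4, 2, 8
        D = rng.standard_normal((n, r))
        M = rng.standard_normal((r, s))
        C, _ = np.linalg.qr(M)
        X = rng.standard_normal((n, p))
        Kd = np.linalg.inv(random_pd_cov(rng, p))
        K = SparsePrecision(sp.csr_matrix(Kd))
        frame = build_frame(X, D, C)
        res = statistic_T(frame, K)
        eq17 = np.trace(np.linalg.inv(frame.G22)
                        @ frame.Gamma2_hat @ Kd @ frame.Gamma2_hat.T)
        eq18 = np.trace(frame.Gamma2_tilde @ Kd @ frame.Gamma2_tilde.T)
        assert res.T_obs == pytest.approx(eq17, rel=1e-10)
        assert res.T_obs == pytest.approx(eq18, rel=1e-10)
        assert res.T_obs == pytest.approx(res.components.sum(), rel=1e-10)

    def test_neighbour_correction_matches_definition(self, rng):
        """(gamma_N)_i = gamma_i - sum_j beta_ij gamma_j with
        beta_ij = -K_ij/K_ii."""
        from ggmdx import conditional_regressions

        p = 6
        Kd = np.linalg.inv(random_pd_cov(rng, p))
        K = SparsePrecision(sp.csr_matrix(Kd))
        X = rng.standard_normal((12, p))
        frame = build_frame(X, two_group_D(6, 6), C_TWO_GROUP)
        res = statistic_T(frame, K)
        cr = conditional_regressions(K)
        gamma = res.gamma[0]
        expected = gamma - np.asarray(cr.beta @ gamma).ravel()
        assert_allclose(res.gamma_nb[0], expected, atol=1e-10)


class TestPermutationNull:
    def test_same_seed_identical_nulls(self, rng):
        X = rng.standard_normal((16, 5))
        K = SparsePrecision(sp.eye(5, format="csr"))
        r1 = permutation_null(X, two_group_D(8, 8), C_TWO_GROUP, K, 50, seed=3)
        r2 = permutation_null(X, two_group_D(8, 8), C_TWO_GROUP, K, 50, seed=3)
        assert_allclose(r1.null_T, r2.null_T)
        assert_allclose(r1.null_de, r2.null_de)

    def test_single_permutation_pvalue_values(self, rng):
        X = rng.standard_normal((10, 4))
        K = SparsePrecision(sp.eye(4, format="csr"))
        r = permutation_null(X, two_group_D(5, 5), C_TWO_GROUP, K, 1, seed=0)
        assert r.pvalue_T in (0.5, 1.0)

    def test_null_block_reduces_to_permuting_rows(self, rng):
        """When D~1 is proportional to a column of ones, the residual
        projector I - D1(D1'D1)^{-1}D1' is permutation invariant, so the
        procedure is exactly a permutation of the rows of X."""
        n = 12
        D = two_group_D(6, 6)
        frame = build_frame(rng.standard_normal((n, 3)), D, C_TWO_GROUP)
        D1 = frame.D_tilde_1
        P1 = D1 @ np.linalg.solve(D1.T @ D1, D1.T)
        assert_allclose(P1, np.ones((n, n)) / n, atol=1e-12)
        perm = rng.permutation(n)
        Pk = np.eye(n)[perm]
        assert_allclose(P1, Pk @ P1 @ Pk.T, atol=1e-12)

    def test_type_i_error_calibration_of_T(self):
        """Under a true null, the permutation p-value of T is approximately
        uniform (checked with a KS test over independent replicates)."""
        import scipy.stats

        model = generate_precision(SimConfig(p=12, n=24, q_per_row=2, seed=61))
        pvals = []
        for rep in range(120):
            X = sample_mvn(model.K_true, 24, seed=1000 + rep)
            res = two_group_test(X, ["a"] * 12 + ["b"] * 12, model.K_true,
                                 q=99, seed=rep)
            pvals.append(res.pvalue_T)
        ks = scipy.stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_standardized_dc_scores_approximately_normal(self):
        """Under the null, (gamma_N)_i * sqrt(K_ii) is approximately
        standard normal: moments checked at 3 sigma."""
        model = generate_precision(SimConfig(p=20, n=40, q_per_row=2, seed=71))
        d = model.K_true.K.diagonal()
        zs = []
        for rep in range(300):
            X = sample_mvn(model.K_true, 40, seed=2000 + rep)
            frame = build_frame(X, two_group_D(20, 20), C_TWO_GROUP)
            res = statistic_T(frame, model.K_true)
            zs.append(res.gamma_nb[0] * np.sqrt(d))
        z = np.concatenate(zs)
        m = z.size
        assert abs(z.mean()) < 3 / np.sqrt(m)
        assert abs(z.var() - 1) < 3 * np.sqrt(2 / m) + 0.05


class TestTwoGroupWrapper:
    def test_agrees_with_general_path_exactly(self, rng):
        X = rng.standard_normal((14, 6))
        Kd = np.linalg.inv(random_pd_cov(rng, 6))
        K = SparsePrecision(sp.csr_matrix(Kd))
        labels = ["t"] * 8 + ["c"] * 6
        r1 = two_group_test(X, labels, K, q=30, seed=9)
        r2 = permutation_null(X, two_group_D(8, 6), C_TWO_GROUP, K, 30, seed=9)
        assert r1.T_obs == pytest.approx(r2.T_obs, rel=1e-14)
        assert_allclose(r1.null_T, r2.null_T)

    def test_label_swap_leaves_T_unchanged(self, rng):
        X = rng.standard_normal((10, 4))
        K = SparsePrecision(sp.eye(4, format="csr"))
        labels = ["a"] * 5 + ["b"] * 5
        swapped = ["b"] * 5 + ["a"] * 5
        t1 = two_group_test(X, labels, K, q=10, seed=0).T_obs
        t2 = two_group_test(X, swapped, K, q=10, seed=0).T_obs
        assert t1 == pytest.approx(t2, rel=1e-12)

    def test_requires_exactly_two_groups(self):
        with pytest.raises(ValueError, match="two group"):
            two_group_design(["a", "b", "c"])


class TestModifiedBonferroni:
    def test_worked_example_threshold(self):
        res = modified_bonferroni(np.full(20000, 0.5), np.full(20000, 0.5),
                                  alpha_expected_fp=8, m_tests=40000)
        assert res.threshold == 8 / 40000 == 0.0002

    def test_alpha_equals_m_rejects_everything_below_one(self):
        p = np.array([0.2, 0.999, 1.0])
        res = modified_bonferroni(p, alpha_expected_fp=3, m_tests=3)
        assert res.threshold == 1.0
        assert res.rejected_de.tolist() == [0, 1]

    def test_all_ones_rejects_nothing(self):
        res = modified_bonferroni(np.ones(10), np.ones(10),
                                  alpha_expected_fp=8)
        assert res.m_tests == 20
        assert res.rejected_de.size == 0 and res.rejected_dc.size == 0
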