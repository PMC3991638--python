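"""Unit and property tests of the sparse Bayesian solvers."""

import numpy as np
import pytest
from scipy.optimize import minimize

import ccell
from ccell.sparse_bayes import BCSConfig, DesignPosterior, SparseLinearProblem

from conftest import exhaustive_l0_support


class TestEStep:
    def test_identity_design_shrinks_observations(self):
        problem = SparseLinearProblem(np.eye(2), [1.0, 0.0], 1.0)
        mean, cov = ccell.bcs_e_step(problem, np.ones(2))
        np.testing.assert_allclose(mean, [0.5, 0.0], atol=1e-12)
        np.testing.assert_allclose(cov, 0.5 * np.eye(2), atol=1e-12)

    def test_huge_precision_forces_zero_mean(self, rng):
        phi = rng.normal(size=(4, 6))
        problem = SparseLinearProblem(phi, rng.normal(size=4), 1.0)
        mean, _ = ccell.bcs_e_step(problem, np.full(6, 1e12))
        assert np.max(np.abs(mean)) < 1e-9

    def test_matches_numerical_map_oracle(self, rng):
        """The closed form must agree with a numerical optimizer of the
        exact log joint density and a finite-difference precision."""
        phi = rng.normal(size=(5, 8))
        g = rng.normal(size=5)
        s2 = 0.5
        alpha = np.ones(8)
        problem = SparseLinearProblem(phi, g, s2)
        mean, cov = ccell.bcs_e_step(problem, alpha)

        def neg_log_post(x):
            resid = g - phi @ x
            return 0.5 * (resid @ resid / s2 + x @ (alpha * x))

        opt = minimize(neg_log_post, np.zeros(8), method="BFGS", tol=1e-12)
        np.testing.assert_allclose(mean, opt.x, atol=1e-6)

        def grad(x):
            return alpha * x - phi.T @ (g - phi @ x) / s2

        eps = 1e-6
        hess = np.empty((8, 8))
        for j in range(8):
            e = np.zeros(8)
            e[j] = eps
            hess[:, j] = (grad(mean + e) - grad(mean - e)) / (2 * eps)
        np.testing.assert_allclose(cov, np.linalg.inv(hess), rtol=1e-5, atol=1e-8)

    def test_invalid_hyperparameters_rejected(self, rng):
        problem = SparseLinearProblem(rng.normal(size=(3, 4)), np.zeros(3), 1.0)
        with pytest.raises(ValueError):
            ccell.bcs_e_step(problem, np.array([1.0, -1.0, 1.0, 1.0]))
        with pytest.raises(ValueError):
            ccell.bcs_e_step(problem, np.full(4, np.inf))


class TestMStep:
    @pytest.mark.parametrize(
        "mean, cov, expected",
        [
            ([1.0], [[0.0]], [1.0]),
            ([0.0, 2.0], np.diag([1.0, 0.0]), [1.0, 0.25]),
        ],
    )
    def test_variational_update(self, mean, cov, expected):
        np.testing.assert_allclose(ccell.bcs_m_step(mean, cov), expected)

    def test_zero_second_moment_hits_prune_threshold(self):
        alpha = ccell.bcs_m_step([0.0], [[0.0]])
        assert alpha[0] == BCSConfig().prune_threshold

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            ccell.bcs_m_step([1.0], [[-0.1]])

    def test_em_fixed_point_self_consistency(self, rng):
        """After alternating E/M to tolerance, one more update is small."""
        phi = rng.normal(size=(6, 12))
        g = phi @ np.concatenate([[1.5, -1.0], np.zeros(10)]) + 0.01 * rng.normal(size=6)
        problem = SparseLinearProblem(phi, g, 1e-3)
        alpha = np.ones(12)
        tol = 1e-4
        for _ in range(20000):
            mean, cov = ccell.bcs_e_step(problem, alpha)
            new = ccell.bcs_m_step(mean, cov)
            delta = np.max(np.abs(np.log(new) - np.log(alpha)))
            alpha = np.minimum(new, 1e12)
            if delta < tol:
                break
        mean, cov = ccell.bcs_e_step(problem, alpha)
        once_more = np.minimum(ccell.bcs_m_step(mean, cov), 1e12)
        assert np.max(np.abs(np.log(once_more) - np.log(alpha))) < tol


class TestBcsEstimate:
    def test_identity_near_noiseless_recovers_sparse_signal(self):
        g = np.zeros(10)
        g[[2, 7]] = [1.0, -1.0]
        post = ccell.bcs_estimate(SparseLinearProblem(np.eye(10), g, 1e-6))
        assert np.max(np.abs(post.mean - g)) < 1e-3
        assert len(post.pruned) >= 8

    def test_zero_observations_prune_everything(self, rng):
        phi = rng.normal(size=(6, 9))
        post = ccell.bcs_estimate(SparseLinearProblem(phi, np.zeros(6), 1e-4))
        np.testing.assert_array_equal(post.mean, np.zeros(9))
        assert len(post.pruned) == 9

    def test_support_matches_exhaustive_l0_oracle(self, rng):
        phi = rng.normal(size=(7, 15))
        phi /= np.linalg.norm(phi, axis=0)
        x = np.zeros(15)
        x[[3, 11]] = [1.0, -2.0]
        g = phi @ x
        post = ccell.bcs_estimate(SparseLinearProblem(phi, g, 1e-10))
        support = set(np.flatnonzero(np.abs(post.mean) > 1e-6))
        assert support == exhaustive_l0_support(phi, g, 2)
        assert support == {3, 11}

    def test_row_permutation_invariance(self, rng):
        phi = rng.normal(size=(8, 12))
        g = rng.normal(size=8)
        post = ccell.bcs_estimate(SparseLinearProblem(phi, g, 1e-2))
        perm = rng.permutation(8)
        post_p = ccell.bcs_estimate(SparseLinearProblem(phi[perm], g[perm], 1e-2))
        np.testing.assert_allclose(post.mean, post_p.mean, atol=1e-8)
        np.testing.assert_allclose(post.covariance, post_p.covariance, atol=1e-8)

    def test_nonconvergence_warns_not_raises(self, rng):
        phi = rng.normal(size=(6, 10))
        g = rng.normal(size=6)
        config = BCSConfig(max_iter=2, update="variational", refine_support=False)
        with pytest.warns(RuntimeWarning):
            post = ccell.bcs_estimate(SparseLinearProblem(phi, g, 1e-4), config)
        assert not post.converged

    def test_posterior_covariance_symmetric_psd(self, rng):
        for _ in range(10):
            m, n = rng.integers(3, 9), rng.integers(3, 14)
            phi = rng.normal(size=(m, n))
            g = rng.normal(size=m)
            post = ccell.bcs_estimate(SparseLinearProblem(phi, g, 1e-2))
            cov = post.covariance
            assert np.max(np.abs(cov - cov.T)) < 1e-10
            trace = max(np.trace(cov), 1e-30)
            assert np.linalg.eigvalsh(cov).min() >= -1e-8 * trace

    def test_deterministic(self, rng):
        phi = rng.normal(size=(6, 10))
        g = rng.normal(size=6)
        a = ccell.bcs_estimate(SparseLinearProblem(phi, g, 1e-3))
        b = ccell.bcs_estimate(SparseLinearProblem(phi, g, 1e-3))
        np.testing.assert_array_equal(a.mean, b.mean)
        np.testing.assert_array_equal(a.hyperparameters, b.hyperparameters)


class TestBlrPosterior:
    def test_data_dominates_with_negligible_noise(self, rng):
        phi = rng.normal(size=(4, 4)) + 2 * np.eye(4)
        g = rng.normal(size=4)
        problem = SparseLinearProblem(phi, g, 1e-12)
        mean, _ = ccell.blr_posterior(problem, np.ones(4), np.eye(4))
        np.testing.assert_allclose(mean, np.linalg.solve(phi, g), atol=1e-5)

    def test_zero_design_returns_prior(self):
        problem = SparseLinearProblem(np.zeros((3, 2)), np.zeros(3), 1.0)
        prior_mean = np.array([0.3, -1.2])
        prior_cov = np.array([[2.0, 0.5], [0.5, 1.0]])
        mean, cov = ccell.blr_posterior(problem, prior_mean, prior_cov)
        np.testing.assert_allclose(mean, prior_mean, atol=1e-10)
        np.testing.assert_allclose(cov, prior_cov, atol=1e-10)

    def test_diffuse_prior_matches_least_squares(self, rng):
        phi = rng.normal(size=(8, 3))
        g = rng.normal(size=8)
        problem = SparseLinearProblem(phi, g, 0.1)
        mean, _ = ccell.blr_posterior(problem, np.zeros(3), 1e8 * np.eye(3))
        ols, *_ = np.linalg.lstsq(phi, g, rcond=None)
        assert np.linalg.norm(mean - ols) / np.linalg.norm(ols) < 1e-3

    def test_non_pd_prior_rejected(self, rng):
        problem = SparseLinearProblem(rng.normal(size=(3, 2)), np.zeros(3), 1.0)
        with pytest.raises(ValueError):
            ccell.blr_posterior(problem, np.zeros(2), -np.eye(2))


class TestExtendedBcs:
    def test_e_step_zero_covariance_equals_plain(self, rng):
        phi = rng.normal(size=(5, 4))
        g = rng.normal(size=5)
        alpha = np.abs(rng.normal(size=4)) + 0.5
        dp = DesignPosterior(phi, np.zeros((5, 4, 4)))
        mean_e, cov_e = ccell.ext_bcs_e_step(dp, g, alpha, 0.3)
        mean_p, cov_p = ccell.bcs_e_step(SparseLinearProblem(phi, g, 0.3), alpha)
        np.testing.assert_array_equal(mean_e, mean_p)
        np.testing.assert_array_equal(cov_e, cov_p)

    def test_e_step_hand_example(self):
        """Single equation, <x> = (1,0)', Cov = diag(1,0), g = 1, alpha = 1,
        sigma^2 = 1: precision = diag(1,1) + <x><x>' + Cov = diag(3, 1)."""
        dp = DesignPosterior([[1.0, 0.0]], [np.diag([1.0, 0.0])])
        mean, cov = ccell.ext_bcs_e_step(dp, [1.0], np.ones(2), 1.0)
        np.testing.assert_allclose(np.linalg.inv(cov), np.diag([3.0, 1.0]), atol=1e-12)
        np.testing.assert_allclose(mean, [1.0 / 3.0, 0.0], atol=1e-12)

    def test_e_step_matches_monte_carlo_expected_precision(self, rng):
        """Sampling designs from the posterior and averaging the exact
        per-sample precision matches the closed-form expectation."""
        k, n = 3, 2
        means = rng.normal(size=(k, n))
        a = rng.normal(size=(k, n, n)) * 0.3
        covs = np.einsum("kij,klj->kil", a, a) + 0.1 * np.eye(n)
        alpha = np.ones(n)
        s2 = 0.7
        dp = DesignPosterior(means, covs)
        _, cov = ccell.ext_bcs_e_step(dp, np.ones(k), alpha, s2)
        precision = np.linalg.inv(cov)
        total = np.zeros((n, n))
        n_samples = 100_000
        for kk in range(k):
            chol = np.linalg.cholesky(covs[kk])
            x = means[kk] + rng.normal(size=(n_samples, n)) @ chol.T
            total += np.einsum("si,sj->ij", x, x) / n_samples
        mc_precision = np.diag(alpha) + total / s2
        np.testing.assert_allclose(precision, mc_precision, rtol=0.01)

    def test_estimate_zero_covariance_bitwise_equal_to_plain(self, rng):
        phi = rng.normal(size=(6, 9))
        g = rng.normal(size=6)
        dp = DesignPosterior(phi, np.zeros((6, 9, 9)))
        ext = ccell.ext_bcs_estimate(dp, g, 1e-3)
        plain = ccell.bcs_estimate(SparseLinearProblem(phi, g, 1e-3))
        np.testing.assert_array_equal(ext.mean, plain.mean)
        np.testing.assert_array_equal(ext.covariance, plain.covariance)
        np.testing.assert_array_equal(ext.hyperparameters, plain.hyperparameters)

    def test_estimate_determined_noiseless_solves_system(self, rng):
        phi = rng.normal(size=(4, 4)) + 3 * np.eye(4)
        w = np.array([1.0, -2.0, 0.5, 3.0])
        g = phi @ w
        dp = DesignPosterior(phi, np.zeros((4, 4, 4)))
        post = ccell.ext_bcs_estimate(dp, g, 1e-12)
        np.testing.assert_allclose(post.mean, w, atol=1e-6)

    def test_design_uncertainty_regularizes(self, rng):
        """Inflating the design covariances acts as extra regularization:
        the posterior mean shrinks and the posterior covariance tightens
        (the expected second moment enters the precision)."""
        k, n = 12, 6
        phi = rng.normal(size=(k, n))
        w = np.zeros(n)
        w[[1, 4]] = [1.2, -0.8]
        g = phi @ w + 0.05 * rng.normal(size=k)
        base = np.array([0.05 * np.eye(n)] * k)
        small = ccell.ext_bcs_estimate(DesignPosterior(phi, base), g, 2.5e-3)
        large = ccell.ext_bcs_estimate(DesignPosterior(phi, 10 * base), g, 2.5e-3)
        assert np.linalg.norm(large.mean) < np.linalg.norm(small.mean)
        assert np.trace(large.covariance) < np.trace(small.covariance)

    def test_dimension_mismatch_rejected(self, rng):
        dp = DesignPosterior(rng.normal(size=(3, 2)), np.zeros((3, 2, 2)))
        with pytest.raises(ValueError):
            ccell.ext_bcs_e_step(dp, np.zeros(4), np.ones(2), 1.0)


class TestProblemValidation:
    def test_all_zero_row_rejected(self):
        with pytest.raises(ValueError):
            SparseLinearProblem([[1.0, 0.0], [0.0, 0.0]], [0.0, 0.0], 1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            SparseLinearProblem(np.eye(3), [1.0, 2.0], 1.0)

    def test_nonpositive_noise_rejected(self):
        with pytest.raises(ValueError):
            SparseLinearProblem(np.eye(2), [0.0, 0.0], 0.0)
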