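import numpy as np
import pytest

import airfusion as af
from airfusion.covariance import CorrelationCache
from airfusion.inference import (PriorSpec, alpha_full_conditional,
                                 geweke_z, nu2_log_density,
                                 phi_full_conditional, restricted_loglik_profile,
                                 rho_log_probs, sample_alpha, sample_nu2,
                                 sample_phi, sample_rho, sample_sigma2,
                                 sigma2_shape_scale)


@pytest.fixture
def toy_system():
    Z = np.array([[1.0, 0.2], [1.0, -1.1], [1.0, 0.7]])
    Y = np.array([0.5, 1.2, -0.3])
    phi = np.array([0.1, -0.2, 0.05])
    return Y, Z, phi


@pytest.fixture
def pair_cache():
    D = np.array([[0.0, 1.0], [1.0, 0.0]])
    return CorrelationCache(D, np.array([0.7]))


class TestSampleAlpha:
    def test_matches_closed_form_moments(self, toy_system):
        Y, Z, phi = toy_system
        s2, n2, pv = 0.3, 0.4, 10.0
        mean, cov = alpha_full_conditional(Y, Z, phi, s2, n2, pv)
        # independent closed form: standard Bayesian linear regression
        prec = Z.T @ Z / (n2 * s2) + np.eye(2) / pv
        np.testing.assert_allclose(cov, np.linalg.inv(prec), atol=1e-12)
        np.testing.assert_allclose(
            mean, np.linalg.solve(prec, Z.T @ (Y - phi) / (n2 * s2)), atol=1e-12)
        rng = np.random.default_rng(0)
        draws = np.array([sample_alpha(Y, Z, phi, s2, n2, pv, rng)
                          for _ in range(4000)])
        se = np.sqrt(np.diag(cov) / 4000)
        assert np.all(np.abs(draws.mean(0) - mean) < 3 * se)
        assert np.abs(np.cov(draws.T) - cov).max() < 3e-3

    def test_flat_prior_limit_is_ols(self, toy_system):
        Y, Z, phi = toy_system
        mean, _ = alpha_full_conditional(Y, Z, phi, 0.3, 0.4, 1e12)
        ols, *_ = np.linalg.lstsq(Z, Y - phi, rcond=None)
        np.testing.assert_allclose(mean, ols, atol=1e-8)

    def test_posterior_variance_shrinks_with_noise(self, toy_system):
        Y, Z, phi = toy_system
        _, cov_hi = alpha_full_conditional(Y, Z, phi, 0.3, 0.4, 10.0)
        _, cov_lo = alpha_full_conditional(Y, Z, phi, 0.03, 0.4, 10.0)
        assert np.trace(cov_lo) < np.trace(cov_hi)


class TestSamplePhi:
    def test_matches_hand_algebra_2x2(self, pair_cache):
        Z = np.ones((2, 1))
        Y = np.array([0.8, -0.3])
        alpha = np.array([0.2])
        s2, n2 = 0.5, 0.3
        S = pair_cache.sigma[0]
        prec = (np.linalg.inv(S) + np.eye(2) / n2) / s2
        mean_hand = np.linalg.solve(prec, (Y - Z @ alpha) / (n2 * s2))
        mean, cov = phi_full_conditional(Y, Z, alpha, s2, n2, S)
        np.testing.assert_allclose(mean, mean_hand, atol=1e-12)
        np.testing.assert_allclose(cov, np.linalg.inv(prec), atol=1e-12)
        rng = np.random.default_rng(1)
        draws = np.array([sample_phi(Y, Z, alpha, s2, n2,
                                     pair_cache.sigma_inv[0], rng)
                          for _ in range(4000)])
        se = np.sqrt(np.diag(cov) / 4000)
        assert np.all(np.abs(draws.mean(0) - mean) < 3 * se)
        assert np.abs(np.cov(draws.T) - cov).max() < 5e-3

    def test_prior_dominates_for_large_nugget(self, pair_cache):
        Y = np.array([5.0, -4.0])
        mean, _ = phi_full_conditional(Y, np.ones((2, 1)), np.zeros(1),
                                       1.0, 1e8, pair_cache.sigma[0])
        np.testing.assert_allclose(mean, 0.0, atol=1e-6)

    def test_zero_residual_gives_small_phi(self, pair_cache):
        rng = np.random.default_rng(2)
        Z = np.ones((2, 1))
        alpha = np.array([0.7])
        Y = Z @ alpha
        draws = np.array([sample_phi(Y, Z, alpha, 1.0, 1e-6,
                                     pair_cache.sigma_inv[0], rng)
                          for _ in range(200)])
        assert np.abs(draws).max() < 0.05

    def test_full_conditional_is_permutation_equivariant(self):
        rng = np.random.default_rng(3)
        coords = rng.uniform(0, 1e4, (6, 2))
        D = af.distance_matrix(coords)
        S = af.exp_correlation(D, 0.4)
        Z = np.column_stack([np.ones(6), rng.standard_normal(6)])
        Y = rng.standard_normal(6)
        alpha = np.array([0.1, -0.2])
        perm = np.array([3, 1, 5, 0, 2, 4])
        mean, cov = phi_full_conditional(Y, Z, alpha, 0.5, 0.3, S)
        mean_p, cov_p = phi_full_conditional(Y[perm], Z[perm], alpha, 0.5, 0.3,
                                             S[np.ix_(perm, perm)])
        np.testing.assert_allclose(mean_p, mean[perm], atol=1e-10)
        np.testing.assert_allclose(cov_p, cov[np.ix_(perm, perm)], atol=1e-10)


class TestSampleSigma2:
    def test_zero_quadratic_forms(self):
        """phi = 0 and Y = Z alpha leave the pure prior-plus-shape update:
        InvGamma(a + m, b)."""
        Z = np.ones((2, 1))
        alpha = np.array([0.4])
        Y = Z @ alpha
        priors = PriorSpec(ig_a=2.0, ig_b=3.0)
        shape, scale = sigma2_shape_scale(Y, Z, alpha, np.zeros(2), 0.3, 0.0,
                                          priors)
        assert shape == pytest.approx(4.0)
        assert scale == pytest.approx(3.0)
        rng = np.random.default_rng(4)
        draws = np.array([sample_sigma2(Y, Z, alpha, np.zeros(2), 0.3, 0.0,
                                        priors, rng) for _ in range(5000)])
        # InvGamma(4, 3) mean = 3/3 = 1, var = 1/2
        assert draws.mean() == pytest.approx(1.0, abs=3 * np.sqrt(0.5 / 5000))

    def test_hand_computed_shape_and_scale(self, pair_cache):
        Y = np.array([1.0, 0.5])
        Z = np.ones((2, 1))
        alpha = np.array([0.2])
        phi = np.array([0.3, -0.1])
        nu2 = 0.5
        quad = float(phi @ pair_cache.sigma_inv[0] @ phi)
        shape, scale = sigma2_shape_scale(Y, Z, alpha, phi, nu2, quad,
                                          PriorSpec())
        resid = Y - Z @ alpha - phi
        assert shape == pytest.approx(0.001 + 2)
        assert scale == pytest.approx(0.001 + 0.5 * (quad + resid @ resid / nu2))


class TestSampleNu2:
    def test_identity_proposal_always_accepted(self):
        rng = np.random.default_rng(5)
        Y = np.array([0.3, -0.2, 0.4])
        Z = np.ones((3, 1))
        new, accepted = sample_nu2(Y, Z, np.zeros(1), np.zeros(3), 0.2, 0.4,
                                   step=0.0, rng=rng)
        assert accepted and new == pytest.approx(0.4)

    def test_long_run_matches_grid_quadrature(self):
        """The MH chain's stationary mean matches the full conditional
        integrated numerically on a fine grid."""
        m, ss, s2 = 5, 0.12, 0.2
        grid = np.linspace(1e-4, 1 - 1e-4, 4001)
        dens = np.exp([nu2_log_density(g, ss, m, s2) for g in grid])
        dens /= np.trapezoid(dens, grid)
        target = np.trapezoid(grid * dens, grid)
        Y = np.full(m, np.sqrt(ss / m))
        Z = np.ones((m, 1))
        rng = np.random.default_rng(6)
        cur, chain = 0.5, []
        for _ in range(30000):
            cur, _ = sample_nu2(Y, Z, np.zeros(1), np.zeros(m), s2, cur, 1.2, rng)
            chain.append(cur)
        chain = np.array(chain[2000:])
        batches = chain[: len(chain) // 50 * 50].reshape(50, -1).mean(axis=1)
        se = batches.std(ddof=1) / np.sqrt(50)
        assert abs(chain.mean() - target) < 4 * se

    def test_adapted_acceptance_rate_in_band(self, small_region):
        """With the default burn-in the adapted logit step yields a
        moderate Metropolis acceptance rate."""
        _, sites, _ = small_region
        fit = af.fit_fusion_model(sites, af.CovariateSpec(), n_burn=500,
                                  n_keep=1000, seed=4)
        assert 0.2 <= fit.posterior.accept_rate_nu2 <= 0.5


class TestSampleRho:
    def test_single_candidate(self, pair_cache):
        rng = np.random.default_rng(7)
        assert sample_rho(np.array([0.1, 0.2]), 0.5, pair_cache, rng) == 0

    def test_frequencies_match_enumeration(self):
        D = np.array([[0.0, 1.0], [1.0, 0.0]])
        cache = CorrelationCache(D, np.array([0.3, 1.0, 2.5]))
        phi = np.array([0.6, -0.4])
        s2 = 0.3
        logp = rho_log_probs(phi, s2, cache)
        probs = np.exp(logp - logp.max())
        probs /= probs.sum()
        rng = np.random.default_rng(8)
        n = 10000
        counts = np.bincount([sample_rho(phi, s2, cache, rng)
                              for _ in range(n)], minlength=3)
        from scipy.stats import chisquare
        assert chisquare(counts, n * probs).pvalue > 1e-3

    def test_zero_phi_leaves_determinant_only(self, pair_cache):
        logp = rho_log_probs(np.zeros(2), 0.5, pair_cache)
        np.testing.assert_allclose(logp, -0.5 * pair_cache.logdet)


class TestRunMcmc:
    def test_deterministic_given_seed(self, small_region):
        _, sites, _ = small_region
        spec = af.CovariateSpec()
        a = af.fit_fusion_model(sites, spec, n_burn=50, n_keep=100, seed=9)
        b = af.fit_fusion_model(sites, spec, n_burn=50, n_keep=100, seed=9)
        np.testing.assert_array_equal(a.posterior.alpha, b.posterior.alpha)
        np.testing.assert_array_equal(a.posterior.phi, b.posterior.phi)
        np.testing.assert_array_equal(a.posterior.rho_index, b.posterior.rho_index)

    def test_exactly_r_factorizations(self, small_fit):
        _, fit = small_fit
        assert fit.posterior.n_factorizations == 50

    def test_retained_states_satisfy_constraints(self, small_fit):
        _, fit = small_fit
        post = fit.posterior
        assert (post.sigma2 > 0).all()
        assert ((post.nu2 > 0) & (post.nu2 < 1)).all()
        assert ((post.rho_index >= 0) & (post.rho_index < 50)).all()

    def test_geweke_flags_trend(self):
        assert abs(geweke_z(np.random.default_rng(0).standard_normal(1000))) < 3
        assert abs(geweke_z(np.linspace(0, 5, 1000)
                            + 0.01 * np.random.default_rng(1).standard_normal(1000))) > 3


class TestREML:
    def test_iid_limit_recovers_ols_residual_variance(self):
        rng = np.random.default_rng(10)
        Z = np.column_stack([np.ones(40), rng.standard_normal(40)])
        Y = Z @ np.array([1.0, 0.5]) + rng.standard_normal(40)
        _, sigma2, alpha, _ = restricted_loglik_profile(Y, Z, np.eye(40))
        ols, *_ = np.linalg.lstsq(Z, Y, rcond=None)
        resid = Y - Z @ ols
        np.testing.assert_allclose(alpha, ols, atol=1e-8)
        assert sigma2 == pytest.approx(resid @ resid / (40 - 2))

    def test_optimum_at_least_generating_likelihood(self, small_region):
        cfg, sites, _ = small_region
        spec = af.CovariateSpec(include_source=True)
        dm = af.build_design_matrix(sites, spec)
        coords = af.jitter_duplicates(
            sites[["easting_m", "northing_m"]].to_numpy())
        D = af.distance_matrix(coords)
        cache = CorrelationCache(D, af.default_rho_grid(D))
        y = np.log(sites["no2_ugm3"].to_numpy())
        fit = af.reml_fit(y, dm.values, cache)
        k_true = int(np.argmin(np.abs(cache.rho_grid - cfg.true_params.rho)))
        ll_true, *_ = restricted_loglik_profile(
            y, dm.values,
            cache.sigma[k_true] + cfg.true_params.nu2 * np.eye(len(y)))
        assert fit.loglik >= ll_true - 1e-6

    def test_consistency_on_well_identified_field(self):
        """With a longer-range decay and several hundred sites, REML
        recovers the generating variance components to within a factor 2."""
        rng = np.random.default_rng(11)
        n = 250
        sites = __import__("pandas").DataFrame({
            "site_id": [f"s{i}" for i in range(n)],
            "easting_m": rng.uniform(0, 10_000, n),
            "northing_m": rng.uniform(0, 10_000, n),
            "source": "tube", "environment": "kerbside",
            "pcm_no2_ugm3": rng.uniform(4, 15, n), "no2_ugm3": 1.0,
        })
        params = af.TrueParams(sigma2=0.3, nu2=0.4, rho=1.0)
        spec = af.CovariateSpec(include_environment=False)
        out = af.simulate_observations(sites, spec, params, seed=12)
        dm = af.build_design_matrix(out, spec)
        coords = out[["easting_m", "northing_m"]].to_numpy()
        D = af.distance_matrix(coords)
        cache = CorrelationCache(D, af.default_rho_grid(D))
        fit = af.reml_fit(np.log(out["no2_ugm3"].to_numpy()), dm.values, cache)
        assert 0.5 * params.sigma2 < fit.sigma2 < 2.0 * params.sigma2
        assert 0.5 * params.nu2 < fit.nu2 < 2.0 * params.nu2
        assert 0.3 * params.rho < fit.rho < 3.0 * params.rho


class TestOLS:
    def test_exact_linear_data(self):
        Z = np.column_stack([np.ones(5), np.arange(5.0)])
        Y = Z @ np.array([2.0, -0.5])
        fit = af.ols_fit(Y, Z)
        np.testing.assert_allclose(fit.alpha, [2.0, -0.5], atol=1e-10)
        np.testing.assert_allclose(fit.result.resid, 0.0, atol=1e-10)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(13)
        Z = np.column_stack([np.ones(30), rng.standard_normal((30, 2))])
        Y = rng.standard_normal(30)
        fit = af.ols_fit(Y, Z)
        np.testing.assert_allclose(
            fit.alpha, np.linalg.solve(Z.T @ Z, Z.T @ Y), atol=1e-10)

    def test_rank_deficiency_rejected(self):
        Z = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(np.linalg.LinAlgError, match="rank deficient"):
            af.ols_fit(np.zeros(10), Z)
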