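"""Matérn covariance, PC priors, posterior density oracle, fitting and kriging."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit, kv, logit

from vaxmono import (
    FitSettings,
    IndicatorDataset,
    IntegrityError,
    MaternParams,
    ModelParams,
    PriorSpec,
    fit,
    log_unnorm_posterior,
    matern_cov,
    matern_cov_matrix,
    pc_prior_rates,
    predict_surface,
)
from vaxmono.geomodel import FitResult, kriging_conditional


def _indicator(rng, m, p_cov=2, coords_scale=8.0):
    n = rng.integers(2, 40, m).astype(float)
    y = n * rng.uniform(0.05, 0.95, m)
    return IndicatorDataset(
        indicator="p1",
        cluster_id=np.array([f"c{i}" for i in range(m)], dtype=object),
        coords=rng.uniform(0, coords_scale, (m, 2)),
        trials=n,
        successes=y,
        covariates=rng.standard_normal((m, p_cov)),
        covariate_names=[f"x{j}" for j in range(p_cov)],
    )


class TestMaternCov:
    def test_zero_distance_is_marginal_variance(self):
        mp = MaternParams(sigma2=2.5, range=3.0)
        assert matern_cov(0.0, mp) == 2.5

    def test_correlation_near_one_tenth_at_effective_range(self):
        mp = MaternParams(sigma2=1.0, range=4.2)
        c = matern_cov(4.2, mp)
        assert 0.10 <= c <= 0.15
        # independent Bessel evaluation: x K_1(x) at x = sqrt(8)
        assert np.isclose(c, np.sqrt(8) * kv(1, np.sqrt(8)), atol=1e-12)

    def test_decay_far_beyond_range(self):
        mp = MaternParams(sigma2=1.0, range=1.0)
        assert matern_cov(100.0, mp) < 1e-6

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            matern_cov(-0.1, MaternParams(1.0, 1.0))

    def test_positive_semidefinite_on_random_point_sets(self, rng):
        for _ in range(25):
            pts = rng.uniform(0, 10, (rng.integers(3, 30), 2))
            mp = MaternParams(sigma2=rng.uniform(0.1, 5), range=rng.uniform(0.1, 10))
            eigs = np.linalg.eigvalsh(matern_cov_matrix(pts, None, mp))
            assert eigs.min() >= -1e-8 * mp.sigma2


class TestPCPriorRates:
    def test_rates_solve_the_tail_statements(self):
        spec = PriorSpec(r0=1.0)
        lam_eps, lam_sigma, lam_r = pc_prior_rates(spec)
        assert np.isclose(lam_eps, -np.log(0.01) / 3)          # ~1.5351
        assert np.isclose(np.exp(-lam_sigma * 3.0), 0.01)       # P(sigma > 3)
        assert np.isclose(np.exp(-lam_r / 1.0), 0.01)           # P(r < r0)
        assert np.isclose(lam_r, 4.60517, atol=1e-4)

    def test_plugback_range_tail_probability(self):
        # P(r < r0) under the density lam r^-2 exp(-lam/r) integrates to alpha
        spec = PriorSpec(r0=2.0, range_alpha=0.05)
        _, _, lam_r = pc_prior_rates(spec)
        from scipy.integrate import quad
        val, _ = quad(lambda r: lam_r * r ** -2 * np.exp(-lam_r / r), 0, spec.r0)
        assert np.isclose(val, 0.05, atol=1e-8)

    def test_alpha_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            PriorSpec(r0=1.0, sigma_alpha=1.5)


def brute_force_log_posterior(params, omega, eps, data, spec):
    """Independent evaluation of the unnormalised log posterior density."""
    m = len(data)
    X = np.column_stack([np.ones(m), data.covariates])
    eta = X @ params.beta + omega + eps
    p = expit(eta)
    lp = float(np.sum(data.successes * np.log(p)
                      + (data.trials - data.successes) * np.log1p(-p)))
    kappa = np.sqrt(8.0) / params.range
    d = np.sqrt(((data.coords[:, None, :] - data.coords[None, :, :]) ** 2).sum(-1))
    with np.errstate(invalid="ignore"):
        corr = np.where(d > 0, kappa * d * kv(1, np.where(d > 0, kappa * d, 1.0)), 1.0)
    Sigma = params.sigma2 * corr + 1e-10 * params.sigma2 * np.eye(m)
    lp += stats.multivariate_normal(mean=np.zeros(m), cov=Sigma).logpdf(omega)
    lp += stats.norm(0, np.sqrt(params.sigma2_eps)).logpdf(eps).sum()
    lp += stats.norm(0, np.sqrt(1.0 / spec.beta_prec)).logpdf(params.beta).sum()
    lam_eps = -np.log(spec.nugget_alpha) / spec.nugget_u
    lam_sigma = -np.log(spec.sigma_alpha) / spec.sigma_u
    lam_r = -spec.r0 * np.log(spec.range_alpha)
    lp += stats.expon(scale=1 / lam_sigma).logpdf(np.sqrt(params.sigma2))
    lp += np.log(lam_r) - 2 * np.log(params.range) - lam_r / params.range
    lp += stats.expon(scale=1 / lam_eps).logpdf(np.sqrt(params.sigma2_eps))
    return float(lp)


class TestLogUnnormPosterior:
    def test_hand_computed_likelihood_term(self):
        # one row, n=2, y=1, eta=0 -> p=1/2, log-lik = ln(1/4); compare the
        # no-latent call against the same density with priors removed by
        # differencing two beta values
        rng = np.random.default_rng(0)
        data = _indicator(rng, 1, p_cov=0)
        data.trials[:] = 2.0
        data.successes[:] = 1.0
        spec = PriorSpec(r0=1.0)
        lp = log_unnorm_posterior(ModelParams([0.0], 1, 1, 1), None, None, data, spec)
        prior_part = lp - np.log(0.25)
        data.successes[:] = 2.0  # now log-lik = 2 ln(1/2)
        lp2 = log_unnorm_posterior(ModelParams([0.0], 1, 1, 1), None, None, data, spec)
        assert np.isclose(lp2 - prior_part, 2 * np.log(0.5), atol=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        spec = PriorSpec(r0=0.7, beta_prec=1e-3)
        for _ in range(20):
            data = _indicator(rng, 5)
            params = ModelParams(
                beta=rng.normal(0, 1, 3),
                sigma2=rng.uniform(0.2, 3),
                range=rng.uniform(0.5, 6),
                sigma2_eps=rng.uniform(0.2, 3),
            )
            omega = rng.normal(0, 1, 5)
            eps = rng.normal(0, 1, 5)
            mine = log_unnorm_posterior(params, omega, eps, data, spec)
            oracle = brute_force_log_posterior(params, omega, eps, data, spec)
            assert np.isclose(mine, oracle, atol=1e-8)

    def test_latent_dimension_mismatch(self, rng):
        data = _indicator(rng, 5)
        with pytest.raises(Exception, match="length"):
            log_unnorm_posterior(ModelParams(np.zeros(3), 1, 1, 1),
                                 np.zeros(4), None, data, PriorSpec(r0=1.0))

    def test_impossible_data_give_minus_infinity(self, rng):
        data = _indicator(rng, 3, p_cov=0)
        params = ModelParams([np.inf], 1, 1, 1)  # p = 1 exactly
        data.successes[:] = data.trials - 1.0    # but some failures observed
        assert log_unnorm_posterior(params, None, None, data, PriorSpec(r0=1.0)) == -np.inf


class TestFit:
    def test_intercept_only_recovers_half(self, rng):
        m = 50
        data = IndicatorDataset(
            indicator="p1",
            cluster_id=np.array([f"c{i}" for i in range(m)], dtype=object),
            coords=rng.uniform(0, 8, (m, 2)),
            trials=np.full(m, 20.0),
            successes=np.full(m, 10.0),
            covariates=np.zeros((m, 0)),
            covariate_names=[],
        )
        fr = fit(data, PriorSpec(r0=0.4), FitSettings(seed=5, n_draws=400, burn=300))
        assert abs(expit(fr.beta[:, 0]).mean() - 0.5) < 0.05

    def test_rank_deficient_design_names_columns(self, rng):
        data = _indicator(rng, 30, p_cov=2)
        data.covariates[:, 1] = 2.0 * data.covariates[:, 0]
        with pytest.raises(IntegrityError, match="x1"):
            fit(data, PriorSpec(r0=0.4), FitSettings(seed=1, n_draws=10, burn=10))

    def test_tiny_dataset_runs_with_warning(self, rng):
        data = _indicator(rng, 5, p_cov=1)
        with pytest.warns(UserWarning):
            fr = fit(data, PriorSpec(r0=0.4), FitSettings(seed=1, n_draws=50, burn=50))
        assert fr.n_draws == 50
        assert np.isfinite(fr.beta).all()

    def test_seed_reproducibility(self, rng):
        data = _indicator(rng, 20)
        a = fit(data, PriorSpec(r0=0.4), FitSettings(seed=7, n_draws=50, burn=50))
        b = fit(data, PriorSpec(r0=0.4), FitSettings(seed=7, n_draws=50, burn=50))
        np.testing.assert_array_equal(a.beta, b.beta)
        np.testing.assert_array_equal(a.u, b.u)

    def test_save_load_round_trip(self, rng, tmp_path):
        data = _indicator(rng, 12)
        fr = fit(data, PriorSpec(r0=0.4), FitSettings(seed=3, n_draws=30, burn=30))
        fr.save(tmp_path / "fit.txt")
        again = FitResult.load(tmp_path / "fit.txt")
        np.testing.assert_allclose(again.beta, fr.beta, rtol=1e-10)
        np.testing.assert_allclose(again.u, fr.u, rtol=1e-10)
        assert again.seed == fr.seed


def _manual_fit_result(u, coords, sigma2=1.3, rng_=2.0, s2e=0.4, S=6):
    m = len(coords)
    return FitResult(
        beta=np.zeros((S, 1)),
        sigma2=np.full(S, sigma2),
        range_=np.full(S, rng_),
        sigma2_eps=np.full(S, s2e),
        u=np.tile(u, (S, 1)),
        coords=np.asarray(coords, float),
        covariate_names=[],
        prior_spec=PriorSpec(r0=0.5),
        seed=0,
    )


class TestPrediction:
    def test_two_point_kriging_matches_closed_form(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0]])
        u = np.array([0.7, -0.2])
        fr = _manual_fit_result(u, coords)
        target = np.array([[0.4, 0.3]])
        mean, cov = kriging_conditional(fr, 0, target)
        mp = MaternParams(1.3, 2.0)
        Sigma = matern_cov_matrix(coords, None, mp) + 0.4 * np.eye(2)
        c = matern_cov_matrix(coords, target, mp)
        mean_o = c.T @ np.linalg.inv(Sigma) @ u
        cov_o = mp.sigma2 - c.T @ np.linalg.inv(Sigma) @ c
        assert np.allclose(mean, mean_o, atol=1e-10)
        assert np.allclose(cov, cov_o, atol=1e-10)

    def test_prediction_at_data_location_with_tiny_nugget(self, rng):
        coords = rng.uniform(0, 4, (6, 2))
        u = rng.normal(0, 1, 6)
        fr = _manual_fit_result(u, coords, s2e=1e-12, S=40)
        targets = type("T", (), {"coords": coords, "covariates": np.zeros((6, 0)),
                                 "covariate_names": []})()
        draws = predict_surface(fr, targets, predict_nugget=False, seed=1)
        np.testing.assert_allclose(draws, expit(np.tile(u, (40, 1))), atol=1e-3)

    def test_far_target_reverts_to_prior(self, rng):
        coords = rng.uniform(0, 1, (5, 2))
        fr = _manual_fit_result(rng.normal(0, 1, 5), coords, sigma2=2.0, rng_=0.5)
        mean, cov = kriging_conditional(fr, 0, np.array([[500.0, 500.0]]))
        assert abs(mean[0]) < 1e-6
        assert np.isclose(cov[0, 0], 2.0, atol=1e-6)

    def test_covariate_mismatch_rejected(self, rng):
        data = _indicator(rng, 12)
        fr = fit(data, PriorSpec(r0=0.4), FitSettings(seed=3, n_draws=20, burn=20))
        bad = type("T", (), {"coords": data.coords, "covariates": data.covariates,
                             "covariate_names": ["wrong", "names"]})()
        with pytest.raises(Exception, match="covariate"):
            predict_surface(fr, bad, seed=0)

    def test_draws_lie_in_unit_interval(self, rng):
        data = _indicator(rng, 15)
        fr = fit(data, PriorSpec(r0=0.4), FitSettings(seed=2, n_draws=40, burn=40))
        targets = type("T", (), {"coords": rng.uniform(0, 8, (9, 2)),
                                 "covariates": rng.standard_normal((9, 2)),
                                 "covariate_names": ["x0", "x1"]})()
        draws = predict_surface(fr, targets, seed=4)
        assert draws.shape == (40, 9)
        assert np.all((draws >= 0) & (draws <= 1))
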