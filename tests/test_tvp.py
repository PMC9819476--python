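"""TVP-VAR Gibbs sampler: reproducibility, constant-parameter reduction,
break tracking, conditional correctness, IRFs and forecasts."""

import numpy as np
import pytest
from scipy import stats

import vegelag as vg
from vegelag.tvp import (
    McmcConfig,
    PosteriorDraws,
    _sample_h_mixture,
    _sample_h_single_move,
    fit_tvp_var,
    tvp_forecast,
    tvp_irf,
)

from conftest import bivariate_panel, constant_dynamics, mc_se


def degenerate_draws(beta_row, k=2, p=1, T=40, n_draws=30, intercept=True):
    """Posterior whose every draw equals the given per-time beta vector."""
    nb = k * (k * p + int(intercept))
    beta = np.tile(np.asarray(beta_row, dtype=float), (n_draws, T, 1))
    assert beta.shape[-1] == nb
    na = k * (k - 1) // 2
    return PosteriorDraws(
        beta=beta, a=np.zeros((n_draws, T, na)), h=np.zeros((n_draws, T, k)),
        sig_beta=np.full((n_draws, nb), 1e-6), sig_a=np.full((n_draws, na), 1e-6),
        sig_h=np.full((n_draws, k), 1e-6),
        variables=tuple(f"y{i}" for i in range(k)), p=p, has_intercept=intercept,
    )


class TestSampler:
    def test_reproducible_given_seed(self):
        panel = bivariate_panel(constant_dynamics(), T=70, seed=3)
        cfg = McmcConfig(iterations=60, burn_in=20, seed=11)
        a = fit_tvp_var(panel, p=1, mcmc=cfg)
        b = fit_tvp_var(panel, p=1, mcmc=cfg)
        assert np.array_equal(a.beta, b.beta)
        assert np.array_equal(a.h, b.h)
        assert np.array_equal(a.sig_beta, b.sig_beta)

    def test_too_short_sample_errors(self):
        panel = bivariate_panel(constant_dynamics(), T=31, seed=0)
        with pytest.raises(ValueError, match="< 30"):
            fit_tvp_var(panel, p=2)

    def test_unknown_ordering_errors(self):
        panel = bivariate_panel(constant_dynamics(), T=70, seed=3)
        with pytest.raises(ValueError, match="unknown"):
            fit_tvp_var(panel, p=1, ordering=("y0", "nope"))

    def test_structural_invariants_every_draw(self, const_draws):
        """A_t is unit lower triangular and h_t finite in every retained draw."""
        assert np.isfinite(const_draws.h).all()
        assert np.isfinite(const_draws.beta).all()
        A = const_draws.contemp_matrix(0, 5)
        assert np.allclose(np.diag(A), 1.0)
        assert np.allclose(np.triu(A, 1), 0.0)
        assert const_draws.n_draws == const_draws.mcmc.n_retained

    def test_convergence_table_shapes(self, const_draws):
        table = const_draws.convergence()
        assert {"mean", "geweke_z", "inefficiency"} <= set(table.columns)
        assert (table["inefficiency"] >= 1.0).all()


class TestConstantReduction:
    def test_beta_path_matches_ols(self, const_panel, const_ols, const_draws):
        """With hyperprior mass near zero variance the posterior mean of every
        beta_t lies within 2 posterior SDs of the OLS estimate."""
        ols_beta = np.column_stack([const_ols.intercept, const_ols.coeffs[0]]).reshape(-1)
        post_mean = const_draws.beta.mean(axis=0)
        post_sd = const_draws.beta.std(axis=0)
        z = np.abs(post_mean - ols_beta[None, :]) / post_sd
        assert z.max() < 2.0

    def test_irf_constant_over_time_and_near_ols_irf(self, const_ols, const_draws):
        t_eff = const_draws.t_eff
        irf = tvp_irf(const_draws, [10, t_eff // 2, t_eff - 10], H=6)
        # constancy: posterior-mean IRFs at distant times agree within 2 MC SEs
        diff = np.abs(irf.mean[0] - irf.mean[2])
        spread = 2.0 * mc_se(_response_draws(const_draws, 10, 6)) \
            + 2.0 * mc_se(_response_draws(const_draws, t_eff - 10, 6))
        assert (diff <= spread + 1e-9).all()
        # agreement with the constant-VAR IRF at horizons 1..6
        ref = vg.var_irf(const_ols, horizon=6).values[:, :, 1:]
        scale = np.maximum(np.abs(ref), 0.2 * np.abs(ref).max())
        rel = np.abs(irf.mean[1, :, :, 1:] - ref) / scale
        assert rel.max() < 0.10

    def test_forecast_matches_var_within_mc_error(self, const_panel, const_ols, const_draws):
        dist = tvp_forecast(const_draws, None, 6)
        ref = vg.var_forecast(const_ols, const_panel, 6)
        paths = _forecast_draws(const_draws, 6)
        se = mc_se(paths)
        assert (np.abs(dist.mean - ref) <= 2.0 * se + 0.01).all()

    def test_break_in_coefficient_is_tracked(self):
        """A mid-sample 0.6 -> -0.6 cross-coefficient break moves the
        posterior path in the planted direction."""
        dyn = vg.DynamicsSpec(
            p=1,
            coeffs=np.array([[0.3, 0.6], [0.0, 0.5]]),
            coeffs_end=np.array([[0.3, -0.6], [0.0, 0.5]]),
            break_month=60, log_vol=np.log(0.01) * np.ones(2),
        )
        panel = bivariate_panel(dyn, T=121, seed=31)
        draws = fit_tvp_var(panel, p=1, mcmc=McmcConfig(500, 150, seed=2))
        path = draws.beta[:, :, 2].mean(axis=0)  # eq y0: [c, b(y0), b(y1)]
        q = len(path) // 4
        assert path[:q].mean() > path[-q:].mean()


def _response_draws(draws, t, H, shock="sd"):
    from vegelag.tvp import _draw_irf

    return np.array([_draw_irf(draws, d, t, H, shock) for d in range(draws.n_draws)])


def _forecast_draws(draws, h):
    out = np.empty((draws.n_draws, h, draws.k))
    tail = draws.history[-draws.p:]
    for d in range(draws.n_draws):
        c, coeffs = draws.coeff_matrices(d, draws.t_eff - 1)
        hist = list(tail)
        for step in range(h):
            mean = c.copy()
            for lag in range(draws.p):
                mean += coeffs[lag] @ hist[-1 - lag]
            out[d, step] = mean
            hist.append(mean)
    return out


class TestHyperparameterConditional:
    def test_variance_draws_match_closed_form(self):
        """With the state path fixed, the sampled innovation variances follow
        the analytic inverse-gamma conditional (KS test on 2000 draws)."""
        rng = np.random.default_rng(12)
        T, true_var = 80, 4e-4
        path = np.cumsum(rng.normal(0.0, np.sqrt(true_var), T))
        diffs = np.diff(path)
        shape0, scale0 = 5.0, 1e-3
        post_shape = shape0 + (T - 1) / 2.0
        post_scale = scale0 + 0.5 * float(diffs @ diffs)
        draws = post_scale / rng.gamma(post_shape, 1.0, size=2000)
        _, pvalue = stats.kstest(draws, stats.invgamma(a=post_shape, scale=post_scale).cdf)
        assert pvalue > 0.01

    def test_mixture_and_single_move_sv_agree(self):
        """The two volatility samplers target the same posterior: long-run
        path means agree to well under one log-variance unit."""
        rng = np.random.default_rng(4)
        T = 120
        e = 0.1 * rng.standard_normal(T)
        log_e2 = np.log(e**2 + 1e-10)
        h_mix = np.full(T, np.log(np.mean(e**2)))
        h_sgl = h_mix.copy()
        rng_m = np.random.default_rng(101)
        rng_s = np.random.default_rng(202)
        mix_sum = np.zeros(T)
        sgl_sum = np.zeros(T)
        n_keep = 300
        for it in range(100 + n_keep):
            h_mix = _sample_h_mixture(log_e2, h_mix, 0.01, 0.0, 10.0, rng_m)
            for _ in range(5):  # single-move mixes slower
                h_sgl = _sample_h_single_move(e, h_sgl, 0.01, 0.0, 10.0, rng_s)
            if it >= 100:
                mix_sum += h_mix
                sgl_sum += h_sgl
        assert abs(mix_sum.mean() / n_keep - sgl_sum.mean() / n_keep) < 0.35
        assert abs(mix_sum.mean() / n_keep - np.log(0.01)) < 0.6


class TestTvpIrf:
    def test_zero_coefficients_zero_propagation(self):
        """All-zero lag coefficients: horizon-0 responses are the impact
        matrix, every later horizon is exactly zero."""
        draws = degenerate_draws(np.zeros(6), T=40)
        irf = tvp_irf(draws, 5, H=4)
        assert np.allclose(irf.mean[0, :, :, 0], np.eye(2))  # h=0, unit sds
        assert np.all(irf.mean[0, :, :, 1:] == 0.0)

    def test_stable_fixture_decays_below_threshold(self, const_draws):
        irf = tvp_irf(const_draws, const_draws.t_eff // 2, H=24)
        assert np.abs(irf.mean[0, :, :, 24]).max() < 0.005

    def test_band_ordering_and_errors(self, const_draws):
        irf = tvp_irf(const_draws, 3, H=4)
        assert (irf.q_lower <= irf.mean + 1e-12).all()
        assert (irf.mean <= irf.q_upper + 1e-12).all()
        with pytest.raises(ValueError, match="outside sample"):
            tvp_irf(const_draws, const_draws.t_eff, H=4)


class TestTvpForecast:
    def test_degenerate_posterior_forecasts_intercept(self):
        beta_row = np.array([0.3, 0.0, 0.0, -0.1, 0.0, 0.0])  # c=(0.3,-0.1), B=0
        draws = degenerate_draws(beta_row, T=40)
        draws.history = np.zeros((1, 2))
        dist = tvp_forecast(draws, None, 5)
        assert np.allclose(dist.mean, np.tile([0.3, -0.1], (5, 1)))

    def test_quantile_bands_monotone(self, const_draws):
        dist = tvp_forecast(const_draws, None, 8)
        assert (dist.quantiles[0.05] <= dist.quantiles[0.5] + 1e-12).all()
        assert (dist.quantiles[0.5] <= dist.quantiles[0.95] + 1e-12).all()

    def test_insufficient_history_errors(self, const_draws):
        with pytest.raises(ValueError, match="at least p"):
            tvp_forecast(const_draws, np.zeros((0, 2)), 3)
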