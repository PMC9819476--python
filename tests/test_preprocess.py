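"""EVI reconstruction chain: MVC, Savitzky-Golay, HANTS."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import vegelag as vg
from vegelag.preprocess import CompositeSeries, HantsParams, SgParams


def harmonic(n, a0=0.4, a1=0.2, theta=0.3, n_period=12):
    i = np.arange(n)
    return a0 + a1 * np.sin(2 * np.pi * i / n_period + theta)


class TestMvc:
    def test_month_maximum(self):
        comps = CompositeSeries(
            pd.DatetimeIndex(["2010-01-03", "2010-01-19"]), np.array([0.41, 0.55])
        )
        out = vg.mvc_monthly(comps)
        assert out.iloc[0] == 0.55

    def test_single_composite_identity(self):
        dates = pd.date_range("2010-01-05", periods=12, freq="MS")
        values = np.linspace(0.1, 0.6, 12)
        out = vg.mvc_monthly(CompositeSeries(dates, values))
        assert np.allclose(out.to_numpy(), values)

    def test_empty_month_errors_with_name(self):
        comps = CompositeSeries(
            pd.DatetimeIndex(["2010-01-03", "2010-03-05"]), np.array([0.4, 0.5])
        )
        with pytest.raises(ValueError, match="2010-02"):
            vg.mvc_monthly(comps)

    def test_mvc_beats_mean_under_low_biased_noise(self):
        """With strictly negative cloud noise the per-month max is closer to
        truth than the per-month mean."""
        idx = pd.date_range("2010-01", periods=36, freq="MS")
        monthly = pd.Series(harmonic(36), index=idx)
        comps = vg.generate_composites(monthly, per_month=2,
                                       cloud_noise=(0.5, 0.2), jitter_sd=0.0, seed=3)
        mvc = vg.mvc_monthly(comps).to_numpy()
        means = comps.to_frame().groupby(comps.dates.to_period("M"))["value"].mean().to_numpy()
        truth = monthly.to_numpy()
        assert np.abs(mvc - truth).mean() < np.abs(means - truth).mean()

    @given(st.floats(-1.0, 1.0))
    @settings(max_examples=25, deadline=None)
    def test_extra_composite_never_lowers_a_month(self, extra):
        dates = pd.DatetimeIndex(["2010-01-03", "2010-01-19"])
        base = vg.mvc_monthly(CompositeSeries(dates, np.array([0.2, 0.3])))
        more = vg.mvc_monthly(
            CompositeSeries(dates.append(pd.DatetimeIndex(["2010-01-28"])),
                            np.array([0.2, 0.3, extra]))
        )
        assert more.iloc[0] >= base.iloc[0]


class TestSgFilter:
    def test_constant_series_unchanged(self):
        out = vg.sg_filter(np.full(20, 0.37), SgParams(2, 2))
        assert np.allclose(out, 0.37)

    def test_exact_on_polynomials_up_to_fit_order(self):
        """An order-2 fit reproduces any quadratic everywhere (shrunk edge
        windows included) to 1e-9."""
        x = np.arange(30, dtype=float)
        series = 0.5 - 0.03 * x + 0.002 * x**2
        for m in (2, 3, 5):
            out = vg.sg_filter(series, SgParams(m, 2))
            assert np.abs(out - series).max() < 1e-9

    def test_center_value_equals_direct_least_squares(self):
        """5-point window oracle: solve the quadratic LS fit explicitly."""
        window = np.array([1.0, 2.0, 6.0, 2.0, 1.0])
        x = np.arange(-2, 3, dtype=float)
        design = np.column_stack([np.ones(5), x, x**2])
        coef, *_ = np.linalg.lstsq(design, window, rcond=None)
        out = vg.sg_filter(window, SgParams(2, 2))
        assert out[2] == pytest.approx(coef[0], abs=1e-12)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=15), rng.normal(size=15)
        params = SgParams(2, 2)
        lhs = vg.sg_filter(2.0 * a + 3.0 * b, params)
        rhs = 2.0 * vg.sg_filter(a, params) + 3.0 * vg.sg_filter(b, params)
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_window_longer_than_series_errors(self):
        with pytest.raises(ValueError, match="shorter"):
            vg.sg_filter(np.ones(3), SgParams(2, 2))
        with pytest.raises(ValueError):
            SgParams(half_width=1, order=3)


class TestHants:
    def test_exact_recovery_of_model_signal(self):
        series = harmonic(60)
        res = vg.hants_reconstruct(series, HantsParams(frequencies=2))
        assert np.abs(res.reconstruction - series).max() < 1e-10
        assert res.outlier_indices == []
        assert res.a0 == pytest.approx(0.4, abs=1e-10)
        assert res.amplitudes[0] == pytest.approx(0.2, abs=1e-10)
        assert res.phases[0] == pytest.approx(0.3, abs=1e-10)

    def test_planted_low_outlier_flagged_and_repaired(self):
        params = HantsParams(frequencies=2)
        series = harmonic(60)
        clean = series.copy()
        series[17] -= 10 * params.fet
        res = vg.hants_reconstruct(series, params)
        assert res.outlier_indices == [17]
        assert abs(res.reconstruction[17] - clean[17]) < params.fet

    def test_constant_series_is_dc_only(self):
        res = vg.hants_reconstruct(np.full(40, 0.25))
        assert res.a0 == pytest.approx(0.25, abs=1e-12)
        assert np.abs(res.amplitudes).max() < 1e-12

    def test_least_squares_local_optimum(self):
        """Perturbing any fitted parameter by 1e-4 does not reduce the RSS
        on the retained points."""
        rng = np.random.default_rng(5)
        series = harmonic(48) + 0.01 * rng.standard_normal(48)
        params = HantsParams(frequencies=2)
        res = vg.hants_reconstruct(series, params)
        i = np.arange(48.0)
        retained = np.setdiff1d(np.arange(48), res.outlier_indices)

        def rss(a0, amps, phases):
            fit = np.full(48, a0)
            for j, (a, th) in enumerate(zip(amps, phases), start=1):
                fit += a * np.sin(2 * np.pi * j / params.base_period * i + th)
            return float(np.sum((series[retained] - fit[retained]) ** 2))

        base = rss(res.a0, res.amplitudes, res.phases)
        for delta in (1e-4, -1e-4):
            assert rss(res.a0 + delta, res.amplitudes, res.phases) >= base - 1e-12
            for j in range(2):
                amps = res.amplitudes.copy(); amps[j] += delta
                assert rss(res.a0, amps, res.phases) >= base - 1e-12
                phs = res.phases.copy(); phs[j] += delta
                assert rss(res.a0, res.amplitudes, phs) >= base - 1e-12

    def test_idempotence(self):
        rng = np.random.default_rng(8)
        series = harmonic(48) + 0.02 * rng.standard_normal(48)
        first = vg.hants_reconstruct(series)
        second = vg.hants_reconstruct(first.reconstruction)
        assert second.outlier_indices == []
        assert np.abs(second.reconstruction - first.reconstruction).max() < 1e-9

    def test_dod_validation(self):
        with pytest.raises(ValueError, match="DOD"):
            HantsParams(frequencies=4, dod=8)
        with pytest.raises(ValueError, match="shorter than DOD"):
            vg.hants_reconstruct(np.ones(6), HantsParams(frequencies=2, dod=8))


class TestSgHants:
    def test_near_identity_on_clean_harmonic(self):
        """With an interpolating SG window (order = window span) the chain is
        exactly identity on a model-matching harmonic; the default smoothing
        order attenuates the annual cycle by well under 1%."""
        series = harmonic(60)
        res = vg.sg_hants(series, sg_params=SgParams(2, 4))
        assert np.abs(res.reconstruction - series).max() < 1e-6
        res_default = vg.sg_hants(series)
        assert np.abs(res_default.reconstruction - series).max() < 2e-3

    def test_reconstruction_beats_raw_mvc(self):
        """On cloud-contaminated composites the SG+HANTS curve is closer to
        the monthly truth than the raw MVC series."""
        idx = pd.date_range("2008-01", periods=60, freq="MS")
        monthly = pd.Series(harmonic(60), index=idx)
        comps = vg.generate_composites(monthly, per_month=2,
                                       cloud_noise=(0.4, 0.15), jitter_sd=0.01, seed=13)
        mvc = vg.mvc_monthly(comps).to_numpy()
        res = vg.sg_hants(mvc)
        truth = monthly.to_numpy()
        assert vg.rmse(res.reconstruction, truth) < vg.rmse(mvc, truth)

    def test_zero_variance_in_zero_variance_out(self):
        res = vg.sg_hants(np.full(36, 0.3))
        assert np.ptp(res.reconstruction) < 1e-12
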