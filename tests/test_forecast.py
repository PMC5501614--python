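"""Parameter-transfer forecasting and peak reporting."""

import numpy as np
import pytest
from scipy.stats import gamma as gamma_dist

from fadspread.forecast import (
    ForecastResult,
    MonotoneMeanError,
    peak_report,
    transfer_forecast,
)
from fadspread.inference import FitConfig, FitResult
from fadspread.series import TrendSeries
from fadspread.synthetic_data import GeneratorSpec, generate_series
from fadspread.trajectory import ObsParams


@pytest.fixture(scope="module")
def source_fit(complex_params_module):
    return FitResult(
        mechanism="complex", n_subpops=1,
        dyn_params=(complex_params_module,),
        obs_params=(ObsParams(A=100.0, delta_t=0.0, r=50.0),),
        log_lik=0.0, k=9, aic=18.0, converged=True, n_restarts_used=0)


@pytest.fixture(scope="module")
def complex_params_module():
    from fadspread.model_core import ComplexDynParams

    return ComplexDynParams(beta=4.0, tau_i=2, tau_j=2, tau_r=2,
                            epsilon=0.5, I0=1e-3)


@pytest.fixture(scope="module")
def target(complex_params_module):
    spec = GeneratorSpec(
        mechanism="complex", dyn=(complex_params_module,),
        obs=(ObsParams(A=100.0, delta_t=0.0, r=50.0),), T=40, seed=77)
    series, truth = generate_series(spec)
    return series, truth


@pytest.fixture(scope="module")
def forecast_cfg():
    return FitConfig(seed=5, n_restarts=4, maxfev_refine=400,
                     maxfev_polish=800)


class TestTransferForecast:
    def test_band_endpoints_are_gamma_quantiles(self, source_fit, target,
                                                forecast_cfg):
        series, _ = target
        early = TrendSeries(name="early", values=series.values[:12])
        fc = transfer_forecast(source_fit, early, horizon=40,
                               config=forecast_cfg)
        assert fc.converged
        r = fc.interval_shape
        assert r < fc.obs_params.r  # dof-corrected band shape
        # independent check through the CDF rather than ppf
        cdf_lo = gamma_dist.cdf(fc.lower95, a=r, scale=fc.mean / r)
        cdf_hi = gamma_dist.cdf(fc.upper95, a=r, scale=fc.mean / r)
        assert np.allclose(cdf_lo, 0.025, atol=1e-8)
        assert np.allclose(cdf_hi, 0.975, atol=1e-8)
        assert np.all(fc.lower95 <= fc.mean)
        assert np.all(fc.mean <= fc.upper95)

    def test_dynamics_are_frozen(self, source_fit, target, forecast_cfg):
        series, _ = target
        early = TrendSeries(name="early", values=series.values[:12])
        fc = transfer_forecast(source_fit, early, horizon=40,
                               config=forecast_cfg)
        src = source_fit.dyn_params[0]
        assert fc.dyn_params.beta == src.beta
        assert (fc.dyn_params.tau_i, fc.dyn_params.tau_j,
                fc.dyn_params.tau_r) == (src.tau_i, src.tau_j, src.tau_r)
        assert fc.dyn_params.epsilon == src.epsilon
        assert fc.dyn_params.I0 != src.I0  # the refit nuisance

    def test_calendar_shift_changes_only_delta_t(self, source_fit, target,
                                                 forecast_cfg):
        """Prepending quiet weeks shifts the fitted time origin, not the
        forecast shape."""
        series, _ = target
        early = TrendSeries(name="early", values=series.values[:12])
        shifted = TrendSeries(name="late",
                              values=np.concatenate([[0.0, 0.0],
                                                     series.values[:12]]))
        fc_a = transfer_forecast(source_fit, early, horizon=40,
                                 config=forecast_cfg)
        fc_b = transfer_forecast(source_fit, shifted, horizon=42,
                                 config=forecast_cfg)
        pk_a = int(np.argmax(fc_a.mean))
        pk_b = int(np.argmax(fc_b.mean))
        assert abs((pk_b - pk_a) - 2) <= 1

    def test_requires_nonzero_early_data(self, source_fit, forecast_cfg):
        empty = TrendSeries(name="flat", values=np.array([0.0, 1.0, 0.0, 2.0]))
        with pytest.raises(ValueError, match="non-zero"):
            transfer_forecast(source_fit, empty, horizon=10,
                              config=forecast_cfg)

    def test_rejects_unconverged_source(self, source_fit, target,
                                        forecast_cfg):
        from dataclasses import replace

        bad = replace(source_fit, converged=False)
        early = TrendSeries(name="early", values=target[0].values[:12])
        with pytest.raises(ValueError, match="converge"):
            transfer_forecast(bad, early, horizon=10, config=forecast_cfg)


class TestPeakReport:
    def _mk(self, mean):
        mean = np.asarray(mean, dtype=float)
        return ForecastResult(
            weeks=np.arange(len(mean), dtype=float), mean=mean,
            lower95=mean * 0.8, upper95=mean * 1.2,
            obs_params=ObsParams(A=1, delta_t=0, r=10), dyn_params=None,
            mechanism="simple", log_lik_early=0.0, converged=True)

    def test_triangular_peak(self):
        # symmetric triangle peaking at week 10; >= half-peak on 6 weeks
        t = np.arange(21.0)
        mean = np.maximum(0.0, 100.0 - 25.0 * np.abs(t - 10))
        fc = self._mk(mean)
        peak, width = peak_report(fc)
        assert peak == 10
        assert width == np.sum(mean >= 50.0)

    def test_flat_zero_mean_errors(self):
        with pytest.raises(MonotoneMeanError):
            peak_report(self._mk(np.zeros(10)))

    def test_monotone_mean_errors(self):
        with pytest.raises(MonotoneMeanError):
            peak_report(self._mk(np.arange(10.0)))

    def test_round_trip_against_generating_trajectory(self, source_fit,
                                                      target, forecast_cfg):
        series, truth = target
        early = TrendSeries(name="early", values=series.values[:14])
        fc = transfer_forecast(source_fit, early, horizon=40,
                               config=forecast_cfg)
        peak, width = peak_report(fc)
        true_peak = int(np.argmax(truth["mean"]))
        assert abs(peak - true_peak) <= 1
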