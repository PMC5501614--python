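"""Gamma likelihood, fitting machinery, AIC and evidence grading."""

import numpy as np
import pytest
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from fadspread.inference import (
    DegenerateSeriesError,
    FitConfig,
    aic,
    compare_models,
    fit_mle,
    gamma_loglik,
    grade_evidence,
    is_multimodal,
    prepare_observations,
)
from fadspread.series import TrendSeries


class TestGammaLoglik:
    def test_matches_scipy_density(self, rng):
        """Mean-shape parameterisation: shape r, scale m/r."""
        for _ in range(100):
            y = rng.uniform(0.1, 100, size=5)
            m = rng.uniform(0.1, 100, size=5)
            r = rng.uniform(0.2, 300)
            want = gamma_dist.logpdf(y, a=r, scale=m / r).sum()
            assert gamma_loglik(y, m, r) == pytest.approx(want, abs=1e-10)

    def test_unit_shape_is_exponential(self, rng):
        y = rng.uniform(0.1, 10, size=8)
        m = rng.uniform(0.1, 10, size=8)
        want = np.sum(-np.log(m) - y / m)
        assert gamma_loglik(y, m, 1.0) == pytest.approx(want, abs=1e-10)

    def test_scale_family_property(self, rng):
        y = rng.uniform(1, 50, size=12)
        m = rng.uniform(1, 50, size=12)
        c = 3.7
        base = gamma_loglik(y, m, 20.0)
        scaled = gamma_loglik(c * y, c * m, 20.0)
        assert scaled == pytest.approx(base - len(y) * np.log(c), abs=1e-9)

    def test_zeros_contribute_censored_mass(self):
        y = np.array([0.0, 5.0])
        m = np.array([0.2, 5.0])
        r = 30.0
        want = (np.log(gammainc(r, r * 0.5 / 0.2))
                + gamma_dist.logpdf(5.0, a=r, scale=5.0 / r))
        assert gamma_loglik(y, m, r) == pytest.approx(want, abs=1e-10)

    def test_invalid_inputs_give_minus_inf(self):
        assert gamma_loglik(np.array([1.0]), np.array([-1.0]), 2.0) == -np.inf
        assert gamma_loglik(np.array([1.0]), np.array([1.0]), -2.0) == -np.inf


class TestCompiledObjective:
    def test_matches_reference_likelihood_route(self, simple_series,
                                                complex_series, fast_cfg):
        """The kernel objective (compiled solve + censored Gamma) must agree
        with the reference route built from trajectory.observation_mean and
        the public gamma_loglik."""
        import math

        from fadspread import _kernels
        from fadspread.inference import _make_objective
        from fadspread.model_core import ComplexDynParams, SimpleDynParams
        from fadspread.trajectory import ObsParams, observation_mean, solve

        coef = _kernels.trinomial_table(10)
        bcoef = _kernels.binomial_table(10)

        series, _ = simple_series
        y = series.values.astype(float)
        obj = _make_objective("simple", y, None, fast_cfg, coef, bcoef)
        x = np.array([np.log(300.0), np.log(80.0), 1.5, np.log(1e-3),
                      np.log(1.1), np.log(0.4), np.log(0.3), np.log(0.5)])
        traj = solve(SimpleDynParams(beta_i=1.1, beta_j=0.4, gamma=0.3,
                                     epsilon=0.5, I0=1e-3), 45.0)
        m = observation_mean(traj, ObsParams(A=300.0, delta_t=1.5, r=80.0),
                             np.arange(len(y), dtype=float))
        ref = -gamma_loglik(y, np.maximum(m, 300.0 * 1e-6), 80.0)
        assert obj(x) == pytest.approx(ref, abs=5e-3)

        series, _ = complex_series
        y = series.values.astype(float)
        obj = _make_objective("complex", y, (2, 2, 2), fast_cfg, coef, bcoef)
        x = np.array([np.log(250.0), np.log(60.0), 0.5, np.log(1e-3),
                      np.log(4.0), np.log(0.5)])
        traj = solve(ComplexDynParams(beta=4.0, tau_i=2, tau_j=2, tau_r=2,
                                      epsilon=0.5, I0=1e-3), 45.0)
        m = observation_mean(traj, ObsParams(A=250.0, delta_t=0.5, r=60.0),
                             np.arange(len(y), dtype=float))
        ref = -gamma_loglik(y, np.maximum(m, 250.0 * 1e-6), 60.0)
        assert obj(x) == pytest.approx(ref, abs=5e-3)

    def test_gradient_matches_central_differences(self, simple_series,
                                                  fast_cfg):
        from fadspread import _kernels
        from fadspread.inference import _make_objective

        coef = _kernels.trinomial_table(10)
        bcoef = _kernels.binomial_table(10)
        y = simple_series[0].values.astype(float)
        obj = _make_objective("simple", y, None, fast_cfg, coef, bcoef)
        x = np.array([np.log(300.0), np.log(80.0), 1.5, np.log(1e-3),
                      np.log(1.1), np.log(0.4), np.log(0.3), np.log(0.5)])
        _, grad = obj.fg(x)
        for i in range(len(x)):
            e = np.zeros_like(x)
            e[i] = 1e-4
            central = (obj(x + e) - obj(x - e)) / 2e-4
            assert grad[i] == pytest.approx(central, rel=0.05, abs=0.5)


class TestAicAndGrades:
    @pytest.mark.parametrize("k,lnL,expected", [(9, 0.0, 18.0),
                                                (8, -10.0, 36.0)])
    def test_aic_formula(self, k, lnL, expected, simple_series, fast_cfg):
        from fadspread.inference import FitResult
        from fadspread.model_core import SimpleDynParams
        from fadspread.trajectory import ObsParams

        fit = FitResult(
            mechanism="simple", n_subpops=1,
            dyn_params=(SimpleDynParams(beta_i=1, beta_j=1, gamma=1,
                                        epsilon=1, I0=0.01),),
            obs_params=(ObsParams(A=1, delta_t=0, r=1),),
            log_lik=lnL, k=k, aic=2 * k - 2 * lnL, converged=True,
            n_restarts_used=1)
        assert aic(fit) == expected
        assert fit.aic == aic(fit)  # stored value is the identity exactly

    @pytest.mark.parametrize("delta,expected", [
        (12.0, "***"), (10.0, "***"), (7.0, "**"), (6.0, "**"),
        (3.0, "*"), (2.0, "*"), (1.9, "."), (0.0, "."), (-1.9, "."),
        (-2.0, "-"), (-8.0, "-"),
    ])
    def test_grade_boundaries(self, delta, expected):
        assert grade_evidence(delta) == expected

    def test_equal_likelihood_pays_the_extra_parameter(self):
        """Same lnL*, single populations: dAIC = 2*(8-9) = -2, no evidence
        for the complex mechanism."""
        delta_aic = (2 * 8 - 2 * (-50.0)) - (2 * 9 - 2 * (-50.0))
        assert delta_aic == -2.0
        assert grade_evidence(delta_aic) == "-"


class TestMultimodality:
    def test_unimodal_not_flagged(self):
        v = np.exp(-0.5 * (np.arange(40.0) - 12) ** 2 / 16) * 100
        assert not is_multimodal(TrendSeries(name="uni", values=v))

    def test_two_peaks_flagged(self):
        t = np.arange(52.0)
        v = (100 * np.exp(-0.5 * (t - 10) ** 2 / 9)
             + 70 * np.exp(-0.5 * (t - 35) ** 2 / 9))
        assert is_multimodal(TrendSeries(name="bi", values=v))

    def test_short_series_not_flagged(self):
        assert not is_multimodal(TrendSeries(name="s", values=np.array(
            [1.0, 100.0, 1.0])))


class TestFitMle:
    def test_degenerate_series_rejected(self):
        with pytest.raises(DegenerateSeriesError):
            prepare_observations(TrendSeries(
                name="dead", values=np.array([0.0, 5.0, 0.0, 0.0])))

    def test_inclusion_filter_enforced(self, fast_cfg):
        sparse = TrendSeries(name="sparse", values=np.array(
            [0.0] * 30 + [50.0, 100.0, 30.0]))
        cfg = FitConfig(seed=0, enforce_filter=True)
        with pytest.raises(ValueError, match="inclusion filter"):
            fit_mle(sparse, "simple", cfg)

    def test_unknown_mechanism(self, simple_series, fast_cfg):
        with pytest.raises(ValueError, match="mechanism"):
            fit_mle(simple_series[0], "viral", fast_cfg)

    def test_simple_fit_smoke(self, simple_series, fast_cfg):
        series, _ = simple_series
        fit = fit_mle(series, "simple", fast_cfg)
        assert fit.converged
        assert fit.k == 8
        assert fit.n_subpops == 1
        assert fit.aic == pytest.approx(2 * 8 - 2 * fit.log_lik)
        assert np.isfinite(fit.log_lik)

    def test_complex_fit_smoke_and_k(self, complex_series, fast_cfg):
        series, _ = complex_series
        fit = fit_mle(series, "complex", fast_cfg)
        assert fit.converged
        assert fit.k == 9
        assert fit.dyn_params[0].tau_i == 2  # only cell in the test grid
        assert fit.aic == pytest.approx(2 * 9 - 2 * fit.log_lik)

    def test_seed_reproducibility(self, simple_series, fast_cfg):
        from dataclasses import replace

        series, _ = simple_series
        a = fit_mle(series, "simple", fast_cfg)
        b = fit_mle(series, "simple", replace(fast_cfg))
        assert a.log_lik == b.log_lik
        assert a.obs_params[0] == b.obs_params[0]

    def test_result_roundtrips_through_json(self, tmp_path, simple_series,
                                            fast_cfg):
        from fadspread.inference import FitResult

        fit = fit_mle(simple_series[0], "simple", fast_cfg)
        path = tmp_path / "fit.json"
        fit.to_json(path)
        back = FitResult.from_json(path)
        assert back == fit


class TestCompareModels:
    def test_returns_grade_and_both_fits(self, complex_series, fast_cfg):
        fc, fs, grade = compare_models(complex_series[0], fast_cfg)
        assert fc.mechanism == "complex"
        assert fs.mechanism == "simple"
        assert grade.delta_aic == pytest.approx(fs.aic - fc.aic)
        assert grade.delta_loglik == pytest.approx(fc.log_lik - fs.log_lik)
        assert grade.grade in {"***", "**", "*", ".", "-"}
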