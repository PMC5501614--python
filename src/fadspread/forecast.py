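"""Out-of-sample forecasting by parameter transfer.

A fad that spread by a similar social mechanism can lend its fitted dynamics
to a new, still-unfolding fad: the mechanism parameters (rates and
thresholds) are frozen from the source fit, while the observation nuisances
and the initial condition (A, delta_t, I0, r) — which depend on population
and measurement scale, not on the mechanism — are refit to the early weeks
of the target.  The forecast is the plug-in mean with a central 95% Gamma
prediction band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import gamma as _gamma_dist

from . import _kernels
from .inference import FitConfig, FitResult, prepare_observations, _BIG
from .inference import _censored_loglik, _mean_on_weeks
from .model_core import ComplexDynParams, SimpleDynParams
from .series import TrendSeries
from .trajectory import ObsParams

__all__ = ["ForecastResult", "transfer_forecast", "peak_report",
           "MonotoneMeanError"]


#: nuisances refit on the early window: A, delta_t, I0, r
_N_REFIT_PARAMS = 4


class MonotoneMeanError(ValueError):
    """Forecast mean has no interior peak, so no peak week can be reported."""


@dataclass
class ForecastResult:
    """Weekly forecast mean with central 95% prediction interval."""

    weeks: np.ndarray
    mean: np.ndarray
    lower95: np.ndarray
    upper95: np.ndarray
    obs_params: ObsParams
    dyn_params: object
    mechanism: str
    log_lik_early: float
    converged: bool
    interval_shape: float = float("nan")  # dof-corrected shape of the band

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "week": self.weeks, "mean": self.mean,
            "lower95": self.lower95, "upper95": self.upper95,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _frozen_dyn_vec(fit: FitResult):
    dp = fit.dyn_params[0]
    if fit.mechanism == "complex":
        taus = (dp.tau_i, dp.tau_j, dp.tau_r)
        rates = (dp.beta, dp.epsilon)
        C = dp.C
    else:
        taus = None
        rates = (dp.beta_i, dp.beta_j, dp.gamma, dp.epsilon)
        C = 10
    return rates, taus, C


def transfer_forecast(source_fit: FitResult, target_early: TrendSeries,
                      horizon: float, config: FitConfig | None = None
                      ) -> ForecastResult:
    """Forecast ``horizon`` weeks of the target fad from transferred dynamics.

    Only (A, delta_t, I0, r) are maximised on ``target_early``; the source
    mechanism's rates and thresholds stay frozen.
    """
    cfg = config or FitConfig()
    if not source_fit.converged:
        raise ValueError("source fit did not converge")
    if target_early.n_nonzero < 3:
        raise ValueError("target_early needs at least 3 non-zero points")
    y = prepare_observations(target_early, cfg)
    T = len(y)
    mech = source_fit.mechanism
    rates, taus, C = _frozen_dyn_vec(source_fit)
    coef = _kernels.trinomial_table(C)
    bcoef = _kernels.binomial_table(C)
    dt_cap = max(2.0 * max(T, horizon), 20.0)

    pos = y > 0
    y_pos = np.ascontiguousarray(y[pos])
    has_zeros = not np.all(pos)

    def neg_loglik(x):
        if np.any(np.abs(np.delete(np.asarray(x, dtype=float), 2)) > 40.0):
            return _BIG
        logA, logr, dt, logI0 = x
        I0 = math.exp(logI0)
        if not I0 < 0.5 or abs(dt) > dt_cap:
            return _BIG
        dyn = rates + (I0,)
        mu = _mean_on_weeks(mech, dyn, taus, C, T, dt, coef, bcoef,
                            cfg.grid_res)
        A = math.exp(logA)
        r = math.exp(logr)
        m = np.maximum(A * mu, cfg.mean_floor_frac * A)
        ll = _kernels.gamma_loglik_arr(y_pos, np.ascontiguousarray(m[pos]), r)
        if has_zeros and np.isfinite(ll):
            ll += _censored_loglik(m[~pos], r, cfg.censor_threshold)
        return -ll if np.isfinite(ll) else _BIG

    rng = np.random.default_rng([cfg.seed, 0xF0])
    best_x, best_f = None, np.inf
    for _ in range(max(cfg.n_restarts, 1)):
        x0 = np.array([
            rng.uniform(*np.log(cfg.amp_range)),
            rng.uniform(*np.log(cfg.shape_range)),
            rng.uniform(-T / 2.0, T / 2.0),
            rng.uniform(*np.log(cfg.i0_range)),
        ])
        res = minimize(neg_loglik, x0, method="L-BFGS-B",
                       options={"maxfun": cfg.maxfev_refine, "eps": 1e-5})
        if res.fun < best_f:
            best_x, best_f = res.x, float(res.fun)
    if best_x is not None and best_f < _BIG / 2:
        from .inference import _polish

        best_x, best_f = _polish(neg_loglik, best_x, best_f,
                                 cfg.maxfev_polish)
    converged = best_x is not None and best_f < _BIG / 2
    if not converged:
        best_x = np.array([math.log(100.0), math.log(10.0), 0.0,
                           math.log(1e-4)])
        best_f = neg_loglik(best_x)

    logA, logr, dt, logI0 = best_x
    A, r, I0 = math.exp(logA), math.exp(logr), math.exp(logI0)
    weeks = np.arange(int(math.ceil(horizon)), dtype=float)
    dyn = rates + (I0,)
    mu = _mean_on_weeks(mech, dyn, taus, C, len(weeks), dt, coef, bcoef,
                        cfg.grid_res)
    mean = np.maximum(A * mu, cfg.mean_floor_frac * A)
    # central 95% of the Gamma observation law at each week.  The maximised
    # shape understates the residual spread when only a few early weeks
    # constrain four free nuisances, so the band uses the degrees-of-
    # freedom-corrected shape r*(T-p)/T — the Gamma analogue of dividing by
    # n-p instead of n when estimating a variance.  The mean stays at the
    # maximum-likelihood value.
    r_band = r * max(T - _N_REFIT_PARAMS, 1) / T
    lower = _gamma_dist.ppf(0.025, a=r_band, scale=mean / r_band)
    upper = _gamma_dist.ppf(0.975, a=r_band, scale=mean / r_band)

    dp = replace(source_fit.dyn_params[0], I0=I0)
    return ForecastResult(
        weeks=weeks, mean=mean, lower95=lower, upper95=upper,
        obs_params=ObsParams(A=A, delta_t=float(dt), r=r),
        dyn_params=dp, mechanism=mech,
        log_lik_early=-best_f, converged=converged,
        interval_shape=float(r_band))


def peak_report(forecast: ForecastResult) -> tuple[int, int]:
    """(peak week, duration) of the forecast mean.

    Duration is the full width at half maximum: the number of consecutive
    weeks, containing the peak, with mean >= 50% of the peak value.
    """
    m = np.asarray(forecast.mean, dtype=float)
    if m.size < 3:
        raise MonotoneMeanError("forecast too short for a peak")
    p = int(np.argmax(m))
    if p == 0 or p == m.size - 1 or m[p] <= 0:
        raise MonotoneMeanError("forecast mean has no interior peak")
    half = 0.5 * m[p]
    lo = p
    while lo > 0 and m[lo - 1] >= half:
        lo -= 1
    hi = p
    while hi < m.size - 1 and m[hi + 1] >= half:
        hi += 1
    return p, hi - lo + 1
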