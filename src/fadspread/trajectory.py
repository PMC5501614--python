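"""Deterministic ODE trajectories and the observation mean A*mu(t + dt).

All solving is done in rescaled units (N = 1): the amplitude parameter A of
the observation model carries the population scale, which removes an
unidentifiable degree of freedom.  Initial condition: S(0) = 1 - I0,
J(0) = R(0) = 0.

Two solver routes are provided: an adaptive high-order scipy integrator
(``method="adaptive"``, relative tolerance 1e-8, the default and reference
route) and a compiled adaptive Cash-Karp RK45 (``method="fast"``), the
kernel the likelihood optimiser relies on for its millions of solves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy.integrate import solve_ivp

from . import _kernels
from .model_core import (
    ComplexDynParams,
    SimpleDynParams,
    binomial_threshold_prob,
    multinomial_threshold_prob,
)

__all__ = [
    "ObsParams",
    "ModelTrajectory",
    "solve",
    "observation_mean",
    "two_population_mean",
]

DynParams = Union[ComplexDynParams, SimpleDynParams]

#: output grid step (weeks)
GRID_DT = 0.1


@dataclass
class ObsParams:
    """Observation nuisance parameters.

    A: relative amplitude mapping model fractions to the 0-100 scale (> 0).
    delta_t: additive shift (weeks); observation at data-time t reads the
        model at t + delta_t, so a larger delta_t moves the fad curve left.
    r: Gamma shape; larger r means less noise at a given mean.
    """

    A: float
    delta_t: float
    r: float

    def __post_init__(self):
        if self.A <= 0 or self.r <= 0:
            raise ValueError("A and r must be positive")


@dataclass
class ModelTrajectory:
    """Solved compartment fractions on a uniform time grid."""

    t: np.ndarray
    S: np.ndarray
    I: np.ndarray
    J: np.ndarray
    R: np.ndarray
    params: DynParams
    n_subpops: int = 1
    method: str = "adaptive"

    @property
    def mu(self) -> np.ndarray:
        """Participation fraction I + J (clamped at 0)."""
        return np.clip(self.I, 0.0, None) + np.clip(self.J, 0.0, None)

    def mechanism(self) -> str:
        return "complex" if isinstance(self.params, ComplexDynParams) else "simple"


class SolverError(RuntimeError):
    """Raised when the ODE solver fails; carries the offending parameters."""

    def __init__(self, message: str, params: DynParams):
        super().__init__(f"{message} (params={params})")
        self.params = params


def _rhs_vector(y: np.ndarray, params: DynParams) -> np.ndarray:
    S, I, J = y
    if isinstance(params, ComplexDynParams):
        f = params.beta * multinomial_threshold_prob(
            I, J, params.C, params.tau_i, params.tau_j
        )
        g2 = binomial_threshold_prob(min(max(J, 0.0), 1.0), params.C, params.tau_r)
        return np.array([-f * S, f * S - params.epsilon * I,
                         params.epsilon * I - g2 * J])
    f = params.beta_i * I + params.beta_j * J
    return np.array([-f * S, f * S - params.epsilon * I,
                     params.epsilon * I - params.gamma * J])


def solve(
    params: DynParams,
    t_max: float,
    dt: float = GRID_DT,
    method: str = "adaptive",
    rtol: float = 1e-8,
) -> ModelTrajectory:
    """Integrate the chosen mechanism from t = 0 to ``t_max`` (weeks).

    The output grid has step ``dt``; R is recovered from conservation.
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    n_out = max(int(np.ceil(t_max / dt)), 2)
    grid = np.linspace(0.0, t_max, n_out + 1)

    if method == "fast":
        if isinstance(params, ComplexDynParams):
            coef = _kernels.trinomial_table(params.C)
            bcoef = _kernels.binomial_table(params.C)
            t, S, I, J = _kernels.rk45_complex(
                params.I0, params.beta, params.epsilon, params.C,
                params.tau_i, params.tau_j, params.tau_r, coef, bcoef,
                t_max, n_out, 1e-7)
        else:
            t, S, I, J = _kernels.rk45_simple(
                params.I0, params.beta_i, params.beta_j, params.gamma,
                params.epsilon, t_max, n_out, 1e-7)
    elif method == "adaptive":
        y0 = np.array([1.0 - params.I0, params.I0, 0.0])
        sol = solve_ivp(
            lambda _t, y: _rhs_vector(y, params),
            (0.0, t_max), y0, method="RK45",
            rtol=rtol, atol=1e-12, dense_output=True)
        if not sol.success:
            raise SolverError(f"ODE solver failed: {sol.message}", params)
        t = grid
        S, I, J = sol.sol(grid)
    else:
        raise ValueError(f"unknown method {method!r}")

    S = np.clip(S, 0.0, None)
    I = np.clip(I, 0.0, None)
    J = np.clip(J, 0.0, None)
    R = np.clip(1.0 - S - I - J, 0.0, None)
    return ModelTrajectory(t=np.asarray(t), S=S, I=I, J=J, R=R,
                           params=params, method=method)


def observation_mean(
    traj: ModelTrajectory, obs: ObsParams, times: np.ndarray
) -> np.ndarray:
    """A * mu(t + delta_t) at the requested observation times.

    Model times before 0 clamp to the initial state; times beyond the solved
    window trigger a re-solve with an extended horizon.
    """
    times = np.asarray(times, dtype=float)
    model_t = times + obs.delta_t
    t_end = traj.t[-1]
    needed = float(np.max(model_t, initial=0.0))
    if needed > t_end + 1e-9:
        traj = solve(traj.params, needed + 1.0,
                     dt=float(traj.t[1] - traj.t[0]), method=traj.method)
    mu = traj.mu
    clamped = np.clip(model_t, 0.0, traj.t[-1])
    return obs.A * np.interp(clamped, traj.t, mu)


def two_population_mean(
    traj_a: ModelTrajectory,
    traj_b: ModelTrajectory,
    obs_a: ObsParams,
    obs_b: ObsParams,
    times: np.ndarray,
) -> np.ndarray:
    """Summed observation mean of two independently seeded sub-populations.

    Both must use the same mechanism; complex pairs must share thresholds
    (the threshold structure is a property of the behaviour, not of who
    adopts it first).
    """
    if traj_a.mechanism() != traj_b.mechanism():
        raise ValueError("sub-populations must share the contagion mechanism")
    if isinstance(traj_a.params, ComplexDynParams):
        pa, pb = traj_a.params, traj_b.params
        if (pa.tau_i, pa.tau_j, pa.tau_r) != (pb.tau_i, pb.tau_j, pb.tau_r):
            raise ValueError("complex sub-populations must share thresholds")
    return observation_mean(traj_a, obs_a, times) + observation_mean(
        traj_b, obs_b, times
    )
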