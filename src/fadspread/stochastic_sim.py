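"""Exact event-driven simulation of the contagion process at finite N.

The continuous-time Markov chain moves one individual at a time:
S -> I at rate S*f, I -> J at rate I*eps, J -> R at rate J*g2 (complex) or
J*gamma (simple).  The direct method is used: sample an exponential waiting
time from the total rate, then pick the event proportionally.  Sample paths
are statistically exact, which the ODE-convergence study relies on: the
ensemble mean approaches the deterministic solution with error O(N^-1/2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd

from . import _kernels
from .model_core import CompartmentState, ComplexDynParams, SimpleDynParams

__all__ = ["EventTrajectory", "simulate", "ensemble_summary"]

#: refuse runs above this population size (memory/time guard)
N_CAP = 10**7

DynParams = Union[ComplexDynParams, SimpleDynParams]


@dataclass
class EventTrajectory:
    """One sample path: event times and integer counts after each event."""

    event_times: np.ndarray
    S: np.ndarray
    I: np.ndarray
    J: np.ndarray
    R: np.ndarray
    N: int
    seed: int

    def __len__(self) -> int:
        return len(self.event_times)

    def state_at(self, t: float) -> tuple[int, int, int, int]:
        """Right-continuous state at time t (last event at or before t)."""
        idx = int(np.searchsorted(self.event_times, t, side="right")) - 1
        idx = max(idx, 0)
        return (int(self.S[idx]), int(self.I[idx]),
                int(self.J[idx]), int(self.R[idx]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.event_times, "S": self.S, "I": self.I,
            "J": self.J, "R": self.R,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def simulate(
    initial: CompartmentState,
    params: DynParams,
    t_max: float,
    seed: int,
) -> EventTrajectory:
    """Run one exact sample path from ``initial`` up to ``t_max`` weeks.

    ``initial`` must carry integer counts.  Rates use the rescaled (N = 1)
    parameters with compartment fractions I/N, J/N, so the same parameter
    values describe the ODE limit.
    """
    counts = initial.as_array()
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("stochastic simulation needs integer counts")
    N = int(round(initial.N))
    if N < 1:
        raise ValueError("N must be >= 1")
    if N > N_CAP:
        raise ValueError(f"N = {N} exceeds the configured cap {N_CAP}")
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    if int(round(initial.J)) or int(round(initial.R)):
        raise ValueError("simulation starts from J = R = 0")
    I0c = int(round(initial.I))

    if isinstance(params, ComplexDynParams):
        coef = _kernels.trinomial_table(params.C)
        bcoef = _kernels.binomial_table(params.C)
        t, S, I, J, R = _kernels.gillespie_complex(
            N, I0c, params.beta, params.epsilon, params.C,
            params.tau_i, params.tau_j, params.tau_r, coef, bcoef,
            float(t_max), int(seed))
    else:
        t, S, I, J, R = _kernels.gillespie_simple(
            N, I0c, params.beta_i, params.beta_j, params.gamma,
            params.epsilon, float(t_max), int(seed))
    return EventTrajectory(event_times=t, S=S, I=I, J=J, R=R, N=N,
                           seed=int(seed))


def ensemble_summary(
    runs: list[EventTrajectory], grid: np.ndarray
) -> dict[str, np.ndarray]:
    """Pointwise mean and SD of each compartment over an ensemble.

    Each run is interpolated onto ``grid`` as a right-continuous step
    function (the state holds between events).
    """
    if len(runs) < 2:
        raise ValueError("ensemble_summary needs at least 2 runs")
    grid = np.asarray(grid, dtype=float)
    comps = {"S": [], "I": [], "J": [], "R": []}
    for run in runs:
        idx = np.searchsorted(run.event_times, grid, side="right") - 1
        idx = np.clip(idx, 0, len(run) - 1)
        comps["S"].append(run.S[idx])
        comps["I"].append(run.I[idx])
        comps["J"].append(run.J[idx])
        comps["R"].append(run.R[idx])
    out: dict[str, np.ndarray] = {"time": grid}
    for name, stack in comps.items():
        arr = np.asarray(stack, dtype=float)
        out[f"{name}_mean"] = arr.mean(axis=0)
        out[f"{name}_sd"] = arr.std(axis=0, ddof=1)
    return out
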