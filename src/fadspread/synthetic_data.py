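"""Synthetic weekly search-interest series with the structure the pipeline
assumes: an ODE participation curve observed through Gamma noise, rescaled
to percent of peak and quantised to integers (small values become zero, as
the real data source rounds them down).

The generator is the sampling dual of the fitting likelihood, so ground
truth is exactly recoverable in expectation; every series is returned with
its generating parameters for recovery scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .model_core import ComplexDynParams, SimpleDynParams
from .series import TrendSeries
from .trajectory import ModelTrajectory, ObsParams, observation_mean, solve

__all__ = ["GeneratorSpec", "generate_series", "generate_benchmark_suite",
           "DegenerateSpecError"]

DynParams = Union[ComplexDynParams, SimpleDynParams]


class DegenerateSpecError(ValueError):
    """The specified mean is numerically zero over the whole window."""


@dataclass
class GeneratorSpec:
    """Everything needed to draw one synthetic fad series."""

    mechanism: str                       # "complex" | "simple"
    dyn: tuple[DynParams, ...]           # one entry per sub-population
    obs: tuple[ObsParams, ...]           # matching observation parameters
    T: int = 40                          # weeks
    seed: int = 0
    rescale_to_peak: bool = True
    quantize: bool = True

    def __post_init__(self):
        if isinstance(self.dyn, (ComplexDynParams, SimpleDynParams)):
            self.dyn = (self.dyn,)
        if isinstance(self.obs, ObsParams):
            self.obs = (self.obs,)
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if len(self.dyn) != len(self.obs) or len(self.dyn) not in (1, 2):
            raise ValueError("dyn and obs must have 1 or 2 matching entries")

    @property
    def n_subpops(self) -> int:
        return len(self.dyn)


def generate_series(spec: GeneratorSpec) -> tuple[TrendSeries, dict]:
    """Draw one series; returns (series, truth).

    truth carries the generating spec, the noiseless weekly mean, the solved
    trajectories and the effective amplitude after percent-of-peak rescaling
    (rescaling by the realised maximum multiplies every A by the same
    random factor; the Gamma shape r is scale-invariant).
    """
    rng = np.random.default_rng(spec.seed)
    times = np.arange(spec.T, dtype=float)
    mean = np.zeros(spec.T)
    trajs: list[ModelTrajectory] = []
    for dp, op in zip(spec.dyn, spec.obs):
        horizon = spec.T + max(op.delta_t, 0.0) + 1.0
        traj = solve(dp, horizon)
        trajs.append(traj)
        mean = mean + observation_mean(traj, op, times)
    if float(mean.max()) < 1e-12:
        raise DegenerateSpecError("observation mean is ~0 over the window")

    r = spec.obs[0].r
    y = rng.gamma(shape=r, scale=np.maximum(mean, 1e-300) / r)

    scale = 1.0
    if spec.rescale_to_peak:
        scale = 100.0 / float(y.max())
        y = y * scale
    if spec.quantize:
        y = np.rint(y)

    series = TrendSeries(name=f"synthetic-{spec.mechanism}-{spec.seed}",
                         values=y)
    truth = {
        "spec": spec,
        "mechanism": spec.mechanism,
        "mean": mean,
        "mean_rescaled": mean * scale,
        "scale": scale,
        "A_effective": tuple(op.A * scale for op in spec.obs),
        "trajectories": trajs,
    }
    return series, truth


# ---------------------------------------------------------------------------
# benchmark suite

#: suite draw ranges: produce peaks and tails at the few-to-tens-of-weeks
#: scale typical of photo fads
SUITE_RATE_RANGE = (0.1, 10.0)
SUITE_TAU_CHOICES = (1, 2, 3, 4)
SUITE_I0_RANGE = (1e-5, 1e-3)
SUITE_SHAPE_CHOICES = (20.0, 50.0, 200.0)


def _draw_dyn(rng: np.random.Generator, mechanism: str) -> DynParams:
    lo, hi = np.log(SUITE_RATE_RANGE)
    if mechanism == "complex":
        return ComplexDynParams(
            beta=float(np.exp(rng.uniform(lo, hi))),
            epsilon=float(np.exp(rng.uniform(lo, hi))),
            tau_i=int(rng.choice(SUITE_TAU_CHOICES)),
            tau_j=int(rng.choice(SUITE_TAU_CHOICES)),
            tau_r=int(rng.choice(SUITE_TAU_CHOICES)),
            I0=float(np.exp(rng.uniform(*np.log(SUITE_I0_RANGE)))),
        )
    return SimpleDynParams(
        beta_i=float(np.exp(rng.uniform(lo, hi))),
        beta_j=float(np.exp(rng.uniform(lo, hi))),
        gamma=float(np.exp(rng.uniform(lo, hi))),
        epsilon=float(np.exp(rng.uniform(lo, hi))),
        I0=float(np.exp(rng.uniform(*np.log(SUITE_I0_RANGE)))),
    )


def _fad_like(series: TrendSeries, mean: np.ndarray, min_nonzero: int) -> bool:
    """Inclusion criteria for the suite: enough non-zero weeks and an actual
    fad (interior rise-and-fall of the noiseless mean, not a bare decay)."""
    if series.n_nonzero <= min_nonzero:
        return False
    p = int(np.argmax(mean))
    if p == 0 or p == len(mean) - 1:
        return False
    return mean[p] > 5.0 * mean[0] and mean[-1] < 0.8 * mean[p]


def generate_benchmark_suite(
    n_fads: int,
    seed: int,
    T: int = 52,
    shape_choices: tuple[float, ...] = SUITE_SHAPE_CHOICES,
    bimodal_frac: float = 0.2,
    min_nonzero: int = 15,
    mechanism: str | None = None,
    max_attempts: int = 200,
) -> list[tuple[TrendSeries, dict]]:
    """A labelled corpus of synthetic fads for recovery studies.

    Mechanisms alternate (or are fixed by ``mechanism``); a fraction of the
    series superpose two sub-populations.  Parameter draws that fail the
    fad-likeness filter are redrawn, mirroring how the real corpus was
    restricted to series with more than ``min_nonzero`` non-zero weeks.
    """
    if n_fads < 1:
        raise ValueError("n_fads must be >= 1")
    out: list[tuple[TrendSeries, dict]] = []
    for i in range(n_fads):
        mech = mechanism or ("complex" if i % 2 == 0 else "simple")
        for attempt in range(max_attempts):
            rng = np.random.default_rng([seed, i, attempt])
            r = float(rng.choice(shape_choices))
            n_subpops = 2 if rng.random() < bimodal_frac else 1
            dyn = []
            obs = []
            for p in range(n_subpops):
                dp = _draw_dyn(rng, mech)
                if mech == "complex" and p == 1:
                    # thresholds are a property of the behaviour: shared
                    d0 = dyn[0]
                    dp = ComplexDynParams(
                        beta=dp.beta, epsilon=dp.epsilon, I0=dp.I0, C=d0.C,
                        tau_i=d0.tau_i, tau_j=d0.tau_j, tau_r=d0.tau_r)
                dyn.append(dp)
                delta_t = float(rng.uniform(-T / 2.0, 0.0)) if p == 1 else \
                    float(rng.uniform(-5.0, 5.0))
                obs.append(ObsParams(A=100.0, delta_t=delta_t, r=r))
            spec = GeneratorSpec(
                mechanism=mech, dyn=tuple(dyn), obs=tuple(obs), T=T,
                seed=int(rng.integers(2**31 - 1)))
            try:
                series, truth = generate_series(spec)
            except DegenerateSpecError:
                continue
            if _fad_like(series, truth["mean"], min_nonzero):
                series.name = f"fad-{i:02d}-{mech}"
                out.append((series, truth))
                break
        else:
            raise RuntimeError(
                f"could not draw a fad-like series for slot {i} "
                f"after {max_attempts} attempts")
    return out
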