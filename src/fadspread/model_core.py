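"""Contagion mechanisms for behavioural fads.

Two mechanisms over the compartments S (susceptible), I (new participant),
J (continuing participant), R (removed):

* **Complex contagion** — each susceptible canvasses ``C`` contacts uniformly
  at random and adopts if at least ``tau_i`` of them are new participants, or
  fewer than ``tau_i`` are new but at least ``tau_j`` are continuing
  participants.  Participants in J quit when at least ``tau_r`` of their
  canvassed contacts are also in J.  The adoption hazard is therefore a tail
  sum of trinomial probabilities and the quit hazard a binomial tail.
* **Simple contagion** — standard mass action: force of adoption
  ``beta_i*I + beta_j*J``, constant per-capita quit rate ``gamma``.

Both share the I -> J transition at constant rate ``epsilon`` (novelty decay)
and have no return to susceptibility (SIR-like, h = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import betainc, comb

__all__ = [
    "CompartmentState",
    "ComplexDynParams",
    "SimpleDynParams",
    "multinomial_threshold_prob",
    "binomial_threshold_prob",
    "complex_rhs",
    "simple_rhs",
]

#: tolerated simplex overshoot from solver drift before raising
SIMPLEX_TOL = 1e-9


@dataclass
class CompartmentState:
    """Population counts (or fractions, with N rescaled to 1) at an instant."""

    S: float
    I: float
    J: float
    R: float
    N: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.N is None:
            self.N = self.S + self.I + self.J + self.R
        if self.N <= 0:
            raise ValueError("population size N must be positive")
        if min(self.S, self.I, self.J, self.R) < -SIMPLEX_TOL:
            raise ValueError("compartment values must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.S, self.I, self.J, self.R], dtype=float)


@dataclass
class ComplexDynParams:
    """Dynamical parameters of the threshold (complex-contagion) mechanism.

    Rates are per week.  ``C`` is the canvass size, fixed at 10 for fitting
    since it is not identifiable from aggregate data.
    """

    beta: float
    tau_i: int
    tau_j: int
    tau_r: int
    epsilon: float
    I0: float
    C: int = 10

    def __post_init__(self):
        if self.beta < 0 or self.epsilon < 0:
            raise ValueError("rates must be non-negative")
        for tau in (self.tau_i, self.tau_j, self.tau_r):
            if not 1 <= tau <= self.C:
                raise ValueError(f"thresholds must lie in [1, C={self.C}]")
        if not 0 < self.I0 < 1:
            raise ValueError("I0 must lie in (0, 1) in rescaled units")


@dataclass
class SimpleDynParams:
    """Dynamical parameters of the mass-action (simple-contagion) mechanism."""

    beta_i: float
    beta_j: float
    gamma: float
    epsilon: float
    I0: float

    def __post_init__(self):
        if min(self.beta_i, self.beta_j, self.gamma, self.epsilon) < 0:
            raise ValueError("rates must be non-negative")
        if not 0 < self.I0 < 1:
            raise ValueError("I0 must lie in (0, 1) in rescaled units")


def _clamp_simplex(i_frac: float, j_frac: float) -> tuple[float, float]:
    """Clamp (i, j) onto the 2-simplex, tolerating tiny solver overshoot."""
    i = min(max(float(i_frac), 0.0), 1.0)
    j = min(max(float(j_frac), 0.0), 1.0)
    s = i + j
    if s > 1.0:
        if s > 1.0 + SIMPLEX_TOL:
            raise ValueError(f"i_frac + j_frac = {s} exceeds 1")
        i, j = i / s, j / s
    return i, j


def _binom_sf(k: int, n: int, p: float) -> float:
    """P(Bin(n, p) >= k) for integer k >= 1, via the regularized beta."""
    if k <= 0:
        return 1.0
    if k > n:
        return 0.0
    return float(betainc(k, n - k + 1, p))


def multinomial_threshold_prob(
    i_frac: float, j_frac: float, C: int, tau_i: int, tau_j: int
) -> float:
    """Probability that a canvass of ``C`` contacts triggers adoption.

    Contacts are drawn with replacement from the population, landing in
    categories (new participant, continuing participant, other) with
    probabilities ``(i_frac, j_frac, 1 - i_frac - j_frac)``.  Adoption fires
    when the count K of new participants reaches ``tau_i``, or K < ``tau_i``
    but the count L of continuing participants reaches ``tau_j``:

        P = sum_{k>=tau_i} sum_l Multi(k, l) + sum_{k<tau_i} sum_{l>=tau_j} Multi(k, l)

    with ``Multi(k, l) = 0`` outside the support ``k + l <= C``.  The first
    block marginalises to a binomial tail; the second factorises through the
    conditional law of L given K.  The adoption *rate* is ``beta`` times this.
    """
    if not (1 <= tau_i <= C and 1 <= tau_j <= C):
        raise ValueError("thresholds must lie in [1, C]")
    i, j = _clamp_simplex(i_frac, j_frac)

    part1 = _binom_sf(tau_i, C, i)

    part2 = 0.0
    one_m_i = 1.0 - i
    for k in range(min(tau_i, C + 1)):
        n_rest = C - k
        if n_rest < tau_j:
            continue
        if one_m_i <= 0.0:
            continue  # all mass at k = C, which is >= tau_i here only if tau_i <= C
        pk = float(comb(C, k)) * i**k * one_m_i**n_rest
        q = min(j / one_m_i, 1.0)  # L | K=k ~ Bin(C-k, j/(1-i))
        part2 += pk * _binom_sf(tau_j, n_rest, q)

    return min(part1 + part2, 1.0)


def binomial_threshold_prob(j_frac: float, C: int, tau_r: int) -> float:
    """Quit probability: upper binomial tail P(Bin(C, j_frac) >= tau_r)."""
    if not 1 <= tau_r <= C:
        raise ValueError("tau_r must lie in [1, C]")
    if not 0.0 <= j_frac <= 1.0 + SIMPLEX_TOL:
        raise ValueError("j_frac must lie in [0, 1]")
    return _binom_sf(tau_r, C, min(j_frac, 1.0))


def complex_rhs(state: CompartmentState, params: ComplexDynParams) -> np.ndarray:
    """ODE right-hand side (dS, dI, dJ, dR)/dt for the complex mechanism.

    dS/dt = -f S,  dI/dt = f S - eps I,  dJ/dt = eps I - g2 J,  dR/dt = g2 J,
    with f = beta * adoption tail probability and g2 the quit tail.
    """
    N = state.N
    f = params.beta * multinomial_threshold_prob(
        state.I / N, state.J / N, params.C, params.tau_i, params.tau_j
    )
    g2 = binomial_threshold_prob(state.J / N, params.C, params.tau_r)
    dS = -f * state.S
    dI = f * state.S - params.epsilon * state.I
    dJ = params.epsilon * state.I - g2 * state.J
    dR = g2 * state.J
    return np.array([dS, dI, dJ, dR])


def simple_rhs(state: CompartmentState, params: SimpleDynParams) -> np.ndarray:
    """ODE right-hand side for the mass-action mechanism (force linear in I, J)."""
    N = state.N
    f = (params.beta_i * state.I + params.beta_j * state.J) / N
    dS = -f * state.S
    dI = f * state.S - params.epsilon * state.I
    dJ = params.epsilon * state.I - params.gamma * state.J
    dR = params.gamma * state.J
    return np.array([dS, dI, dJ, dR])
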