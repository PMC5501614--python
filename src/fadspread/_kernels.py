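"""Compiled inner loops: threshold hazards, fixed-step ODE integration,
Gamma log-likelihood, and exact event-driven simulation.

These kernels exist so that a single likelihood evaluation (ODE solve +
likelihood) costs well under a millisecond inside the optimiser, and so that
stochastic ensembles at N = 1e5 run at desk scale.  The public modules
(`model_core`, `trajectory`) remain the reference implementations; tests
assert agreement between the two routes.

Power tables are carried as caller-allocated workspaces so the per-step cost
is pure arithmetic.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = [
    "trinomial_table",
    "binomial_table",
    "complex_adoption_prob",
    "binom_tail",
    "rk45_complex",
    "rk45_simple",
    "gamma_loglik_arr",
    "gillespie_complex",
    "gillespie_simple",
]


def trinomial_table(C: int) -> np.ndarray:
    """coef[k, l] = C! / (k! l! (C-k-l)!) for k + l <= C, else 0."""
    coef = np.zeros((C + 1, C + 1))
    for k in range(C + 1):
        for l in range(C + 1 - k):
            coef[k, l] = math.comb(C, k) * math.comb(C - k, l)
    return coef


def binomial_table(C: int) -> np.ndarray:
    """bcoef[y] = C choose y."""
    return np.array([math.comb(C, y) for y in range(C + 1)], dtype=float)


@njit(cache=True, inline="always")
def _adoption_prob_ws(i, j, C, tau_i, tau_j, coef, pi, pj, pr):
    """Two-part trinomial tail: P(K >= tau_i) + P(K < tau_i, L >= tau_j).

    pi/pj/pr are length C+1 scratch arrays for the power tables.
    """
    if i < 0.0:
        i = 0.0
    if j < 0.0:
        j = 0.0
    s = i + j
    if s > 1.0:
        i /= s
        j /= s
    rest = 1.0 - i - j
    if rest < 0.0:
        rest = 0.0
    pi[0] = 1.0
    pj[0] = 1.0
    pr[0] = 1.0
    for n in range(1, C + 1):
        pi[n] = pi[n - 1] * i
        pj[n] = pj[n - 1] * j
        pr[n] = pr[n - 1] * rest
    total = 0.0
    for k in range(tau_i, C + 1):
        for l in range(0, C - k + 1):
            total += coef[k, l] * pi[k] * pj[l] * pr[C - k - l]
    for k in range(0, tau_i):
        for l in range(tau_j, C - k + 1):
            total += coef[k, l] * pi[k] * pj[l] * pr[C - k - l]
    if total > 1.0:
        total = 1.0
    return total


@njit(cache=True, inline="always")
def _binom_tail_ws(j, C, tau_r, bcoef, pj, pq):
    """P(Bin(C, j) >= tau_r) by direct summation (pj/pq are scratch)."""
    if j <= 0.0:
        return 0.0
    if j > 1.0:
        j = 1.0
    q = 1.0 - j
    pj[0] = 1.0
    pq[0] = 1.0
    for n in range(1, C + 1):
        pj[n] = pj[n - 1] * j
        pq[n] = pq[n - 1] * q
    total = 0.0
    for y in range(tau_r, C + 1):
        total += bcoef[y] * pj[y] * pq[C - y]
    if total > 1.0:
        total = 1.0
    return total


@njit(cache=True)
def complex_adoption_prob(i, j, C, tau_i, tau_j, coef):
    """Allocating convenience wrapper around the workspace kernel."""
    pi = np.empty(C + 1)
    pj = np.empty(C + 1)
    pr = np.empty(C + 1)
    return _adoption_prob_ws(i, j, C, tau_i, tau_j, coef, pi, pj, pr)


@njit(cache=True)
def binom_tail(j, C, tau_r, bcoef):
    pj = np.empty(C + 1)
    pq = np.empty(C + 1)
    return _binom_tail_ws(j, C, tau_r, bcoef, pj, pq)


@njit(cache=True, inline="always")
def _complex_deriv(S, I, J, beta, eps, C, ti, tj, tr, coef, bcoef,
                   w1, w2, w3):
    f = beta * _adoption_prob_ws(I, J, C, ti, tj, coef, w1, w2, w3)
    g2 = _binom_tail_ws(J, C, tr, bcoef, w1, w2)
    return -f * S, f * S - eps * I, eps * I - g2 * J


@njit(cache=True, inline="always")
def _simple_deriv(S, I, J, bi, bj, gam, eps):
    f = bi * I + bj * J
    return -f * S, f * S - eps * I, eps * I - gam * J


# Cash-Karp embedded Runge-Kutta 5(4) coefficients
_B21 = 1.0 / 5.0
_B31, _B32 = 3.0 / 40.0, 9.0 / 40.0
_B41, _B42, _B43 = 3.0 / 10.0, -9.0 / 10.0, 6.0 / 5.0
_B51, _B52, _B53, _B54 = -11.0 / 54.0, 5.0 / 2.0, -70.0 / 27.0, 35.0 / 27.0
_B61, _B62, _B63, _B64, _B65 = (1631.0 / 55296.0, 175.0 / 512.0,
                                575.0 / 13824.0, 44275.0 / 110592.0,
                                253.0 / 4096.0)
_C1, _C3, _C4, _C6 = 37.0 / 378.0, 250.0 / 621.0, 125.0 / 594.0, 512.0 / 1771.0
_E1 = _C1 - 2825.0 / 27648.0
_E3 = _C3 - 18575.0 / 48384.0
_E4 = _C4 - 13525.0 / 55296.0
_E5 = -277.0 / 14336.0
_E6 = _C6 - 1.0 / 4.0

_ATOL = 1e-10
_MAX_STEPS = 2_000_000  # failsafe against pathological parameter corners


@njit(cache=True)
def rk45_complex(I0, beta, eps, C, ti, tj, tr, coef, bcoef, t_end, n_out,
                 rtol=1e-7):
    """Adaptive Cash-Karp RK45 in rescaled (N = 1) units, landing exactly on
    a uniform output grid of n_out + 1 points covering [0, t_end].

    R = 1 - S - I - J.  Steps never exceed the grid spacing, so sampling is
    exact (no dense-output interpolation).
    """
    tg = np.empty(n_out + 1)
    So = np.empty(n_out + 1)
    Io = np.empty(n_out + 1)
    Jo = np.empty(n_out + 1)
    w1 = np.empty(C + 1)
    w2 = np.empty(C + 1)
    w3 = np.empty(C + 1)
    S = 1.0 - I0
    I = I0
    J = 0.0
    out_dt = t_end / n_out
    tg[0] = 0.0
    So[0], Io[0], Jo[0] = S, I, J
    h = out_dt
    n_steps = 0
    for g in range(1, n_out + 1):
        t_target = g * out_dt
        t = (g - 1) * out_dt
        while t < t_target - 1e-12 and n_steps < _MAX_STEPS:
            n_steps += 1
            if h > t_target - t:
                h = t_target - t
            a1, b1, c1 = _complex_deriv(S, I, J, beta, eps, C, ti, tj, tr,
                                        coef, bcoef, w1, w2, w3)
            a2, b2, c2 = _complex_deriv(
                S + h * _B21 * a1, I + h * _B21 * b1, J + h * _B21 * c1,
                beta, eps, C, ti, tj, tr, coef, bcoef, w1, w2, w3)
            a3, b3, c3 = _complex_deriv(
                S + h * (_B31 * a1 + _B32 * a2),
                I + h * (_B31 * b1 + _B32 * b2),
                J + h * (_B31 * c1 + _B32 * c2),
                beta, eps, C, ti, tj, tr, coef, bcoef, w1, w2, w3)
            a4, b4, c4 = _complex_deriv(
                S + h * (_B41 * a1 + _B42 * a2 + _B43 * a3),
                I + h * (_B41 * b1 + _B42 * b2 + _B43 * b3),
                J + h * (_B41 * c1 + _B42 * c2 + _B43 * c3),
                beta, eps, C, ti, tj, tr, coef, bcoef, w1, w2, w3)
            a5, b5, c5 = _complex_deriv(
                S + h * (_B51 * a1 + _B52 * a2 + _B53 * a3 + _B54 * a4),
                I + h * (_B51 * b1 + _B52 * b2 + _B53 * b3 + _B54 * b4),
                J + h * (_B51 * c1 + _B52 * c2 + _B53 * c3 + _B54 * c4),
                beta, eps, C, ti, tj, tr, coef, bcoef, w1, w2, w3)
            a6, b6, c6 = _complex_deriv(
                S + h * (_B61 * a1 + _B62 * a2 + _B63 * a3 + _B64 * a4 + _B65 * a5),
                I + h * (_B61 * b1 + _B62 * b2 + _B63 * b3 + _B64 * b4 + _B65 * b5),
                J + h * (_B61 * c1 + _B62 * c2 + _B63 * c3 + _B64 * c4 + _B65 * c5),
                beta, eps, C, ti, tj, tr, coef, bcoef, w1, w2, w3)
            dS = h * (_C1 * a1 + _C3 * a3 + _C4 * a4 + _C6 * a6)
            dI = h * (_C1 * b1 + _C3 * b3 + _C4 * b4 + _C6 * b6)
            dJ = h * (_C1 * c1 + _C3 * c3 + _C4 * c4 + _C6 * c6)
            eS = h * (_E1 * a1 + _E3 * a3 + _E4 * a4 + _E5 * a5 + _E6 * a6)
            eI = h * (_E1 * b1 + _E3 * b3 + _E4 * b4 + _E5 * b5 + _E6 * b6)
            eJ = h * (_E1 * c1 + _E3 * c3 + _E4 * c4 + _E5 * c5 + _E6 * c6)
            err = 0.0
            sc = _ATOL + rtol * abs(S)
            if abs(eS) / sc > err:
                err = abs(eS) / sc
            sc = _ATOL + rtol * abs(I)
            if abs(eI) / sc > err:
                err = abs(eI) / sc
            sc = _ATOL + rtol * abs(J)
            if abs(eJ) / sc > err:
                err = abs(eJ) / sc
            if err <= 1.0:
                t += h
                S += dS
                I += dI
                J += dJ
                if S < 0.0:
                    S = 0.0
                if I < 0.0:
                    I = 0.0
                if J < 0.0:
                    J = 0.0
                fac = 5.0 if err == 0.0 else 0.9 * err ** -0.2
                if fac > 5.0:
                    fac = 5.0
                h *= fac
            else:
                fac = 0.9 * err ** -0.25
                if fac < 0.1:
                    fac = 0.1
                h *= fac
            if h > out_dt:
                h = out_dt
            if h < 1e-10:
                h = 1e-10
        tg[g] = t_target
        So[g], Io[g], Jo[g] = S, I, J
    return tg, So, Io, Jo


@njit(cache=True)
def rk45_simple(I0, bi, bj, gam, eps, t_end, n_out, rtol=1e-7):
    """Adaptive Cash-Karp RK45 for the mass-action mechanism."""
    tg = np.empty(n_out + 1)
    So = np.empty(n_out + 1)
    Io = np.empty(n_out + 1)
    Jo = np.empty(n_out + 1)
    S = 1.0 - I0
    I = I0
    J = 0.0
    out_dt = t_end / n_out
    tg[0] = 0.0
    So[0], Io[0], Jo[0] = S, I, J
    h = out_dt
    n_steps = 0
    for g in range(1, n_out + 1):
        t_target = g * out_dt
        t = (g - 1) * out_dt
        while t < t_target - 1e-12 and n_steps < _MAX_STEPS:
            n_steps += 1
            if h > t_target - t:
                h = t_target - t
            a1, b1, c1 = _simple_deriv(S, I, J, bi, bj, gam, eps)
            a2, b2, c2 = _simple_deriv(
                S + h * _B21 * a1, I + h * _B21 * b1, J + h * _B21 * c1,
                bi, bj, gam, eps)
            a3, b3, c3 = _simple_deriv(
                S + h * (_B31 * a1 + _B32 * a2),
                I + h * (_B31 * b1 + _B32 * b2),
                J + h * (_B31 * c1 + _B32 * c2), bi, bj, gam, eps)
            a4, b4, c4 = _simple_deriv(
                S + h * (_B41 * a1 + _B42 * a2 + _B43 * a3),
                I + h * (_B41 * b1 + _B42 * b2 + _B43 * b3),
                J + h * (_B41 * c1 + _B42 * c2 + _B43 * c3), bi, bj, gam, eps)
            a5, b5, c5 = _simple_deriv(
                S + h * (_B51 * a1 + _B52 * a2 + _B53 * a3 + _B54 * a4),
                I + h * (_B51 * b1 + _B52 * b2 + _B53 * b3 + _B54 * b4),
                J + h * (_B51 * c1 + _B52 * c2 + _B53 * c3 + _B54 * c4),
                bi, bj, gam, eps)
            a6, b6, c6 = _simple_deriv(
                S + h * (_B61 * a1 + _B62 * a2 + _B63 * a3 + _B64 * a4 + _B65 * a5),
                I + h * (_B61 * b1 + _B62 * b2 + _B63 * b3 + _B64 * b4 + _B65 * b5),
                J + h * (_B61 * c1 + _B62 * c2 + _B63 * c3 + _B64 * c4 + _B65 * c5),
                bi, bj, gam, eps)
            dS = h * (_C1 * a1 + _C3 * a3 + _C4 * a4 + _C6 * a6)
            dI = h * (_C1 * b1 + _C3 * b3 + _C4 * b4 + _C6 * b6)
            dJ = h * (_C1 * c1 + _C3 * c3 + _C4 * c4 + _C6 * c6)
            eS = h * (_E1 * a1 + _E3 * a3 + _E4 * a4 + _E5 * a5 + _E6 * a6)
            eI = h * (_E1 * b1 + _E3 * b3 + _E4 * b4 + _E5 * b5 + _E6 * b6)
            eJ = h * (_E1 * c1 + _E3 * c3 + _E4 * c4 + _E5 * c5 + _E6 * c6)
            err = 0.0
            sc = _ATOL + rtol * abs(S)
            if abs(eS) / sc > err:
                err = abs(eS) / sc
            sc = _ATOL + rtol * abs(I)
            if abs(eI) / sc > err:
                err = abs(eI) / sc
            sc = _ATOL + rtol * abs(J)
            if abs(eJ) / sc > err:
                err = abs(eJ) / sc
            if err <= 1.0:
                t += h
                S += dS
                I += dI
                J += dJ
                if S < 0.0:
                    S = 0.0
                if I < 0.0:
                    I = 0.0
                if J < 0.0:
                    J = 0.0
                fac = 5.0 if err == 0.0 else 0.9 * err ** -0.2
                if fac > 5.0:
                    fac = 5.0
                h *= fac
            else:
                fac = 0.9 * err ** -0.25
                if fac < 0.1:
                    fac = 0.1
                h *= fac
            if h > out_dt:
                h = out_dt
            if h < 1e-10:
                h = 1e-10
        tg[g] = t_target
        So[g], Io[g], Jo[g] = S, I, J
    return tg, So, Io, Jo


@njit(cache=True)
def gamma_loglik_arr(y, m, r):
    """Sum of Gamma(mean m_t, shape r) log densities; -inf on bad input."""
    if r <= 0.0:
        return -np.inf
    total = 0.0
    lgr = math.lgamma(r)
    for t in range(y.shape[0]):
        mt = m[t]
        yt = y[t]
        if mt <= 0.0 or yt <= 0.0:
            return -np.inf
        total += r * np.log(r / mt) + (r - 1.0) * np.log(yt) - r * yt / mt - lgr
    return total


@njit(cache=True)
def gillespie_complex(N, I0c, beta, eps, C, ti, tj, tr, coef, bcoef, t_max, seed):
    """Exact (direct-method) sample path of the complex-contagion chain.

    Counts are integers; rates are S*f(I/N, J/N), I*eps, J*g2(J/N) with the
    N = 1 rescaled beta.  Returns event times and counts including the
    initial state.
    """
    np.random.seed(seed)
    cap = 3 * N + 2
    times = np.empty(cap)
    Ss = np.empty(cap, dtype=np.int64)
    Is = np.empty(cap, dtype=np.int64)
    Js = np.empty(cap, dtype=np.int64)
    Rs = np.empty(cap, dtype=np.int64)
    w1 = np.empty(C + 1)
    w2 = np.empty(C + 1)
    w3 = np.empty(C + 1)
    S = N - I0c
    I = I0c
    J = 0
    R = 0
    t = 0.0
    n = 0
    times[n] = t
    Ss[n], Is[n], Js[n], Rs[n] = S, I, J, R
    n += 1
    invN = 1.0 / N
    while n < cap:
        f = beta * _adoption_prob_ws(I * invN, J * invN, C, ti, tj,
                                     coef, w1, w2, w3)
        a1 = S * f
        a2 = I * eps
        a3 = J * _binom_tail_ws(J * invN, C, tr, bcoef, w1, w2)
        a0 = a1 + a2 + a3
        if a0 <= 0.0:
            break
        t += np.random.exponential(1.0 / a0)
        if t > t_max:
            break
        u = np.random.random() * a0
        if u < a1:
            S -= 1
            I += 1
        elif u < a1 + a2:
            I -= 1
            J += 1
        else:
            J -= 1
            R += 1
        times[n] = t
        Ss[n], Is[n], Js[n], Rs[n] = S, I, J, R
        n += 1
    return times[:n], Ss[:n], Is[:n], Js[:n], Rs[:n]


@njit(cache=True)
def gillespie_simple(N, I0c, bi, bj, gam, eps, t_max, seed):
    """Exact sample path of the mass-action chain (rates S*(bi I + bj J)/N)."""
    np.random.seed(seed)
    cap = 3 * N + 2
    times = np.empty(cap)
    Ss = np.empty(cap, dtype=np.int64)
    Is = np.empty(cap, dtype=np.int64)
    Js = np.empty(cap, dtype=np.int64)
    Rs = np.empty(cap, dtype=np.int64)
    S = N - I0c
    I = I0c
    J = 0
    R = 0
    t = 0.0
    n = 0
    times[n] = t
    Ss[n], Is[n], Js[n], Rs[n] = S, I, J, R
    n += 1
    invN = 1.0 / N
    while n < cap:
        a1 = S * (bi * I + bj * J) * invN
        a2 = I * eps
        a3 = J * gam
        a0 = a1 + a2 + a3
        if a0 <= 0.0:
            break
        t += np.random.exponential(1.0 / a0)
        if t > t_max:
            break
        u = np.random.random() * a0
        if u < a1:
            S -= 1
            I += 1
        elif u < a1 + a2:
            I -= 1
            J += 1
        else:
            J -= 1
            R += 1
        times[n] = t
        Ss[n], Is[n], Js[n], Rs[n] = S, I, J, R
        n += 1
    return times[:n], Ss[:n], Is[:n], Js[:n], Rs[:n]


@njit(cache=True)
def gammainc_lower(a, x):
    """Regularized lower incomplete gamma P(a, x) (series / Lentz CF)."""
    if x <= 0.0:
        return 0.0
    if x < a + 1.0:
        ap = a
        s = 1.0 / a
        delta = s
        for _ in range(300):
            ap += 1.0
            delta *= x / ap
            s += delta
            if abs(delta) < abs(s) * 1e-15:
                break
        return s * math.exp(-x + a * math.log(x) - math.lgamma(a))
    b = x + 1.0 - a
    c = 1e300
    d = 1.0 / b
    h = d
    for i in range(1, 300):
        an = -i * (i - a)
        b += 2.0
        d = an * d + b
        if abs(d) < 1e-300:
            d = 1e-300
        c = b + an / c
        if abs(c) < 1e-300:
            c = 1e-300
        d = 1.0 / d
        de = d * c
        h *= de
        if abs(de - 1.0) < 1e-15:
            break
    q = math.exp(-x + a * math.log(x) - math.lgamma(a)) * h
    return 1.0 - q


_INVALID = 1e12


@njit(cache=True)
def negll_complex(x, ti, tj, tr, C, coef, bcoef, y, grid_res, rtol,
                  mean_floor_frac, censor, dt_cap, max_log_rate):
    """Full negative log-likelihood of the threshold model in one call.

    x = (log A, log r, dt, log I0, log beta, log eps); zero weeks enter as
    censored mass below ``censor``.  Returns 1e12 outside the valid region.
    """
    for idx in (0, 1, 3, 4, 5):
        if abs(x[idx]) > 40.0:
            return _INVALID
    if x[4] > max_log_rate or x[5] > max_log_rate:
        return _INVALID
    dt = x[2]
    if abs(dt) > dt_cap:
        return _INVALID
    A = math.exp(x[0])
    r = math.exp(x[1])
    I0 = math.exp(x[3])
    if I0 >= 0.5 or r > 1e7:
        return _INVALID
    beta = math.exp(x[4])
    eps = math.exp(x[5])
    T = y.shape[0]
    # snap the grid to fixed multiples of grid_res so the objective stays
    # continuous in dt (a dt-dependent grid injects finite jumps that wreck
    # finite-difference gradients)
    t_raw = (T - 1) + (dt if dt > 0.0 else 0.0) + 1.0
    n_out = int(math.ceil(t_raw / grid_res))
    if n_out < 2:
        n_out = 2
    t_end = n_out * grid_res
    tg, S, I, J = rk45_complex(I0, beta, eps, C, ti, tj, tr, coef, bcoef,
                               t_end, n_out, rtol)
    out_dt = t_end / n_out
    floor = mean_floor_frac * A
    total = 0.0
    lgr = math.lgamma(r)
    for t in range(T):
        mt = t + dt
        if mt < 0.0:
            mt = 0.0
        if mt > t_end:
            mt = t_end
        pos = mt / out_dt
        g = int(pos)
        if g >= n_out:
            g = n_out - 1
        frac = pos - g
        mu = (I[g] + J[g]) * (1.0 - frac) + (I[g + 1] + J[g + 1]) * frac
        if mu < 0.0:
            mu = 0.0
        m = A * mu
        if m < floor:
            m = floor
        yt = y[t]
        if yt > 0.0:
            total += r * math.log(r / m) + (r - 1.0) * math.log(yt) \
                - r * yt / m - lgr
        else:
            p = gammainc_lower(r, r * censor / m)
            if p < 1e-300:
                p = 1e-300
            total += math.log(p)
    if not np.isfinite(total):
        return _INVALID
    return -total


@njit(cache=True)
def negll_simple(x, y, grid_res, rtol, mean_floor_frac, censor, dt_cap,
                 max_log_rate):
    """As negll_complex for mass action:
    x = (log A, log r, dt, log I0, log bi, log bj, log gam, log eps)."""
    for idx in (0, 1, 3, 4, 5, 6, 7):
        if abs(x[idx]) > 40.0:
            return _INVALID
    for idx in (4, 5, 6, 7):
        if x[idx] > max_log_rate:
            return _INVALID
    dt = x[2]
    if abs(dt) > dt_cap:
        return _INVALID
    A = math.exp(x[0])
    r = math.exp(x[1])
    I0 = math.exp(x[3])
    if I0 >= 0.5 or r > 1e7:
        return _INVALID
    bi = math.exp(x[4])
    bj = math.exp(x[5])
    gam = math.exp(x[6])
    eps = math.exp(x[7])
    T = y.shape[0]
    t_raw = (T - 1) + (dt if dt > 0.0 else 0.0) + 1.0
    n_out = int(math.ceil(t_raw / grid_res))
    if n_out < 2:
        n_out = 2
    t_end = n_out * grid_res  # fixed-grid snap; see negll_complex
    tg, S, I, J = rk45_simple(I0, bi, bj, gam, eps, t_end, n_out, rtol)
    out_dt = t_end / n_out
    floor = mean_floor_frac * A
    total = 0.0
    lgr = math.lgamma(r)
    for t in range(T):
        mt = t + dt
        if mt < 0.0:
            mt = 0.0
        if mt > t_end:
            mt = t_end
        pos = mt / out_dt
        g = int(pos)
        if g >= n_out:
            g = n_out - 1
        frac = pos - g
        mu = (I[g] + J[g]) * (1.0 - frac) + (I[g + 1] + J[g + 1]) * frac
        if mu < 0.0:
            mu = 0.0
        m = A * mu
        if m < floor:
            m = floor
        yt = y[t]
        if yt > 0.0:
            total += r * math.log(r / m) + (r - 1.0) * math.log(yt) \
                - r * yt / m - lgr
        else:
            p = gammainc_lower(r, r * censor / m)
            if p < 1e-300:
                p = 1e-300
            total += math.log(p)
    if not np.isfinite(total):
        return _INVALID
    return -total


@njit(cache=True)
def negll_complex_fg(x, ti, tj, tr, C, coef, bcoef, y, grid_res, rtol,
                     mean_floor_frac, censor, dt_cap, max_log_rate, eps_fd):
    """Value and forward-difference gradient in one compiled call."""
    f0 = negll_complex(x, ti, tj, tr, C, coef, bcoef, y, grid_res, rtol,
                       mean_floor_frac, censor, dt_cap, max_log_rate)
    grad = np.zeros(6)
    if f0 < _INVALID / 2.0:
        for i in range(6):
            xi = x.copy()
            xi[i] += eps_fd
            fi = negll_complex(xi, ti, tj, tr, C, coef, bcoef, y, grid_res,
                               rtol, mean_floor_frac, censor, dt_cap,
                               max_log_rate)
            grad[i] = (fi - f0) / eps_fd
    return f0, grad


@njit(cache=True)
def negll_simple_fg(x, y, grid_res, rtol, mean_floor_frac, censor, dt_cap,
                    max_log_rate, eps_fd):
    f0 = negll_simple(x, y, grid_res, rtol, mean_floor_frac, censor,
                      dt_cap, max_log_rate)
    grad = np.zeros(8)
    if f0 < _INVALID / 2.0:
        for i in range(8):
            xi = x.copy()
            xi[i] += eps_fd
            fi = negll_simple(xi, y, grid_res, rtol, mean_floor_frac,
                              censor, dt_cap, max_log_rate)
            grad[i] = (fi - f0) / eps_fd
    return f0, grad
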