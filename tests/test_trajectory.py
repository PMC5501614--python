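"""ODE trajectories and observation means."""

import numpy as np
import pytest
from dataclasses import replace

from fadspread.model_core import ComplexDynParams, SimpleDynParams
from fadspread.trajectory import (
    ObsParams,
    observation_mean,
    solve,
    two_population_mean,
)


class TestSolve:
    @pytest.mark.parametrize("method", ["adaptive", "fast"])
    def test_linear_decay_closed_form(self, method):
        """With no adoption the I compartment decays as I0 * exp(-eps t)."""
        eps, I0 = 0.7, 0.01
        for params in (
            ComplexDynParams(beta=0.0, tau_i=2, tau_j=2, tau_r=2,
                             epsilon=eps, I0=I0),
            SimpleDynParams(beta_i=0.0, beta_j=0.0, gamma=1.0,
                            epsilon=eps, I0=I0),
        ):
            traj = solve(params, 10.0, method=method)
            expected = I0 * np.exp(-eps * traj.t)
            assert np.allclose(traj.I, expected, rtol=1e-5, atol=1e-12)
            assert np.allclose(traj.S, 1 - I0, rtol=1e-9)

    def test_susceptibles_never_increase(self, complex_params, simple_params):
        for params in (complex_params, simple_params):
            traj = solve(params, 40.0)
            assert np.all(np.diff(traj.S) <= 1e-10)

    def test_conservation_on_grid(self, complex_params):
        traj = solve(complex_params, 40.0)
        total = traj.S + traj.I + traj.J + traj.R
        assert np.allclose(total, 1.0, atol=1e-7)

    def test_fast_route_agrees_with_adaptive(self, complex_params,
                                             simple_params):
        """Compiled RK45 and scipy dense-output solve the same problem."""
        for params in (complex_params, simple_params):
            a = solve(params, 40.0, method="adaptive")
            b = solve(params, 40.0, method="fast")
            assert np.max(np.abs(a.mu - b.mu)) < 1e-5

    def test_grid_halving_only_changes_interpolation(self, complex_params):
        coarse = solve(complex_params, 40.0, dt=0.1)
        fine = solve(complex_params, 40.0, dt=0.05)
        shared = fine.mu[::2]
        denom = np.maximum(np.abs(coarse.mu), 1e-9)
        assert np.max(np.abs(coarse.mu - shared) / denom) < 1e-6

    def test_invalid_horizon(self, simple_params):
        with pytest.raises(ValueError):
            solve(simple_params, -1.0)


class TestObservationMean:
    def test_identity_at_unit_amplitude(self, complex_params):
        traj = solve(complex_params, 40.0)
        times = np.arange(40.0)
        mu = observation_mean(traj, ObsParams(A=1.0, delta_t=0.0, r=10), times)
        assert np.allclose(mu, np.interp(times, traj.t, traj.mu))

    def test_amplitude_linearity(self, complex_params):
        traj = solve(complex_params, 40.0)
        times = np.arange(40.0)
        m1 = observation_mean(traj, ObsParams(A=3.0, delta_t=0.0, r=10), times)
        m2 = observation_mean(traj, ObsParams(A=6.0, delta_t=0.0, r=10), times)
        assert np.allclose(m2, 2 * m1)

    def test_positive_shift_moves_curve_left(self, complex_params):
        traj = solve(complex_params, 60.0)
        times = np.arange(40.0)
        base = observation_mean(traj, ObsParams(A=1, delta_t=0.0, r=10), times)
        shifted = observation_mean(traj, ObsParams(A=1, delta_t=2.0, r=10),
                                   times)
        assert np.argmax(shifted) == np.argmax(base) - 2

    def test_extends_solution_when_needed(self, simple_params):
        traj = solve(simple_params, 10.0)
        times = np.arange(30.0)
        mu = observation_mean(traj, ObsParams(A=1, delta_t=5.0, r=10), times)
        assert mu.shape == (30,)
        assert np.all(mu >= 0)

    def test_strictly_positive_with_seeded_fad(self, simple_params):
        traj = solve(simple_params, 50.0)
        mu = observation_mean(traj, ObsParams(A=1, delta_t=0.0, r=10),
                              np.arange(40.0))
        assert np.all(mu > 0)


class TestTwoPopulationMean:
    def test_zero_amplitude_reduces_to_single(self, simple_params):
        traj = solve(simple_params, 40.0)
        times = np.arange(40.0)
        obs = ObsParams(A=100.0, delta_t=0.0, r=10)
        # amplitude has no true zero (A > 0); use a negligible second pop
        tiny = ObsParams(A=1e-12, delta_t=0.0, r=10)
        combined = two_population_mean(traj, traj, obs, tiny, times)
        single = observation_mean(traj, obs, times)
        assert np.allclose(combined, single, rtol=1e-9)

    def test_mechanism_mismatch_raises(self, simple_params, complex_params):
        ts = solve(simple_params, 10.0)
        tc = solve(complex_params, 10.0)
        obs = ObsParams(A=1, delta_t=0, r=10)
        with pytest.raises(ValueError, match="mechanism"):
            two_population_mean(ts, tc, obs, obs, np.arange(5.0))

    def test_threshold_mismatch_raises(self, complex_params):
        other = replace(complex_params, tau_i=3)
        ta = solve(complex_params, 10.0)
        tb = solve(other, 10.0)
        obs = ObsParams(A=1, delta_t=0, r=10)
        with pytest.raises(ValueError, match="threshold"):
            two_population_mean(ta, tb, obs, obs, np.arange(5.0))

    def test_well_separated_peaks_are_bimodal(self, complex_params):
        traj = solve(complex_params, 80.0)
        times = np.arange(60.0)
        obs_a = ObsParams(A=100.0, delta_t=0.0, r=10)
        obs_b = ObsParams(A=80.0, delta_t=-30.0, r=10)
        combined = two_population_mean(traj, traj, obs_a, obs_b, times)
        m_a = observation_mean(traj, obs_a, times)
        m_b = observation_mean(traj, obs_b, times)
        assert np.allclose(combined, m_a + m_b)
        pk_a, pk_b = np.argmax(m_a), np.argmax(m_b)
        assert abs(pk_b - pk_a) > 20  # two distinct modes
        # each sub-population's peak survives in the sum
        assert combined[pk_a] > 0.8 * m_a.max()
        assert combined[pk_b] > 0.8 * m_b.max()
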