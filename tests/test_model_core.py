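"""Threshold hazards and ODE right-hand sides."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fadspread.model_core import (
    CompartmentState,
    ComplexDynParams,
    SimpleDynParams,
    binomial_threshold_prob,
    complex_rhs,
    multinomial_threshold_prob,
    simple_rhs,
)
from fadspread.studies import enumeration_binomial, enumeration_multinomial


class TestThresholdProbabilities:
    @pytest.mark.parametrize("args,expected", [
        ((0.0, 0.0, 10, 2, 2), 0.0),   # nobody participating, threshold >= 1
        ((1.0, 0.0, 2, 2, 2), 1.0),    # every contact is a new participant
        ((0.0, 1.0, 10, 2, 1), 1.0),   # tau_j=1 fires on continuing contacts
    ])
    def test_degenerate_compositions(self, args, expected):
        assert multinomial_threshold_prob(*args) == pytest.approx(expected)

    @pytest.mark.parametrize("j,C,tau_r,expected", [
        (0.0, 10, 4, 0.0),
        (1.0, 10, 4, 1.0),
    ])
    def test_binomial_degenerate(self, j, C, tau_r, expected):
        assert binomial_threshold_prob(j, C, tau_r) == pytest.approx(expected)

    def test_matches_exhaustive_enumeration(self, rng):
        """Closed-form tails equal brute-force trinomial/binomial sums."""
        for C in range(1, 11):
            for _ in range(20):
                i, j = rng.dirichlet([1, 1, 1])[:2]
                ti = int(rng.integers(1, C + 1))
                tj = int(rng.integers(1, C + 1))
                got = multinomial_threshold_prob(i, j, C, ti, tj)
                want = enumeration_multinomial(i, j, C, ti, tj)
                assert got == pytest.approx(want, abs=1e-12)
                tr = int(rng.integers(1, C + 1))
                assert binomial_threshold_prob(j, C, tr) == pytest.approx(
                    enumeration_binomial(j, C, tr), abs=1e-12)

    def test_unit_threshold_closed_form(self, rng):
        """tau_i = tau_j = 1: adoption iff any canvassed contact participates."""
        for _ in range(50):
            i, j = rng.dirichlet([1, 1, 1])[:2]
            C = int(rng.integers(1, 11))
            got = multinomial_threshold_prob(i, j, C, 1, 1)
            assert got == pytest.approx(1 - (1 - i - j) ** C, abs=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(st.floats(0, 0.5), st.floats(0, 0.5), st.floats(0, 0.4),
           st.integers(1, 10), st.integers(1, 10))
    def test_monotone_in_new_participants(self, i, di, j, ti, tj):
        """The adoption tail never decreases when more contacts participate."""
        C = 10
        if i + di + j > 1:
            return
        lo = multinomial_threshold_prob(i, j, C, ti, tj)
        hi = multinomial_threshold_prob(i + di, j, C, ti, tj)
        assert hi >= lo - 1e-12

    @settings(max_examples=100, deadline=None)
    @given(st.floats(0, 0.5), st.floats(0, 0.5), st.integers(1, 10))
    def test_binomial_monotone(self, j, dj, tr):
        if j + dj > 1:
            return
        assert (binomial_threshold_prob(j + dj, 10, tr)
                >= binomial_threshold_prob(j, 10, tr) - 1e-12)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            multinomial_threshold_prob(0.8, 0.8, 10, 2, 2)
        with pytest.raises(ValueError):
            multinomial_threshold_prob(0.1, 0.1, 10, 0, 2)
        with pytest.raises(ValueError):
            binomial_threshold_prob(0.1, 10, 11)

    def test_simplex_drift_is_clamped(self):
        # tiny solver overshoot must not raise
        val = multinomial_threshold_prob(0.6, 0.4 + 5e-10, 10, 2, 2)
        assert 0 <= val <= 1


class TestRightHandSides:
    def test_fad_free_fixed_point(self, complex_params, simple_params):
        state = CompartmentState(S=1.0, I=0.0, J=0.0, R=0.0)
        assert np.allclose(complex_rhs(state, complex_params), 0)
        assert np.allclose(simple_rhs(state, simple_params), 0)

    def test_conservation_at_random_states(self, rng, complex_params,
                                           simple_params):
        """Total population derivative is exactly zero everywhere."""
        for _ in range(1000):
            fracs = rng.dirichlet([1, 1, 1, 1])
            state = CompartmentState(*fracs)
            assert abs(complex_rhs(state, complex_params).sum()) < 1e-14
            assert abs(simple_rhs(state, simple_params).sum()) < 1e-14

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            ComplexDynParams(beta=-1, tau_i=2, tau_j=2, tau_r=2,
                             epsilon=1, I0=0.01)
        with pytest.raises(ValueError):
            ComplexDynParams(beta=1, tau_i=11, tau_j=2, tau_r=2,
                             epsilon=1, I0=0.01)
        with pytest.raises(ValueError):
            SimpleDynParams(beta_i=1, beta_j=1, gamma=1, epsilon=1, I0=1.5)


class TestEarlyGrowthLimits:
    """Super-exponential vs exponential takeoff in the large-N regime."""

    def test_complex_tracks_finite_time_blowup(self):
        from fadspread.studies import early_growth_errors

        errs = early_growth_errors()
        assert errs["complex"] < 1e-3

    def test_simple_tracks_exponential(self):
        from fadspread.studies import early_growth_errors

        errs = early_growth_errors()
        assert errs["simple"] < 1e-3
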