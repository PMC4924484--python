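"""Forward photocycle machinery: ODE, closed forms, steady states."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from crykinetics.exceptions import DomainError
from crykinetics.kinetics import (
    RateConstants,
    ReoxidationCurveParams,
    StateVector,
    half_life,
    photocycle_derivative,
    reoxidation_decay,
    simulate_photocycle,
    steady_state,
    two_state_concentrations,
)

rates_st = st.floats(min_value=0.0, max_value=0.1, allow_nan=False)


class TestStateVector:
    def test_rejects_negative_and_unnormalized(self):
        with pytest.raises(DomainError):
            StateVector(-0.1, 0.6, 0.5)
        with pytest.raises(DomainError):
            StateVector(0.5, 0.4, 0.3)

    def test_dark_state(self):
        assert StateVector.dark().as_array().tolist() == [1.0, 0.0, 0.0]


class TestDerivative:
    @pytest.mark.parametrize(
        "state, rates, expected",
        [
            # no dynamics at all
            ((1, 0, 0), (0, 0, 0, 0), (0, 0, 0)),
            # single active photoreduction term
            ((1, 0, 0), (0.01, 0, 0, 0), (-0.01, 0.01, 0)),
            # radical both photoreduced onward and reoxidized back
            ((0, 1, 0), (0, 0.02, 0.005, 0), (0.005, -0.025, 0.02)),
        ],
    )
    def test_hand_evaluated_examples(self, state, rates, expected):
        deriv = photocycle_derivative(StateVector(*state), RateConstants(*rates))
        assert deriv == pytest.approx(expected, abs=1e-15)

    @given(k1=rates_st, k2=rates_st, k1b=rates_st, k2b=rates_st,
           rad=st.floats(0, 1), split=st.floats(0, 1))
    @settings(derandomize=True, max_examples=100)
    def test_total_concentration_is_conserved(self, k1, k2, k1b, k2b, rad, split):
        ox = (1 - rad) * split
        state = StateVector(ox, rad, 1 - rad - ox)
        deriv = photocycle_derivative(state, RateConstants(k1, k2, k1b, k2b))
        assert abs(sum(deriv)) < 1e-12

    def test_rejects_negative_rates(self):
        with pytest.raises(DomainError):
            RateConstants(-0.01, 0, 0, 0)


class TestSimulate:
    def test_equilibrium_stays_put(self):
        traj = simulate_photocycle(
            RateConstants(0, 0, 0, 0), StateVector.dark(), [1.0, 10.0, 500.0]
        )
        assert np.allclose(traj.states, [[1, 0, 0]] * 3, atol=1e-15)

    def test_two_state_closed_form_agreement(self):
        # with k2 = k2b = 0 the radical follows the two-state solution
        traj = simulate_photocycle(
            RateConstants(0.01, 0, 0.003, 0), StateVector.dark(), [100.0]
        )
        expected = (0.01 / 0.013) * (1 - math.exp(-0.013 * 100))
        assert traj.fadh_rad[-1] == pytest.approx(expected, abs=1e-6)
        assert traj.fadh_rad[-1] == pytest.approx(
            two_state_concentrations(0.01, 0.003, 100.0)[1], abs=1e-6
        )

    def test_matches_matrix_exponential_oracle(self):
        rates = RateConstants(0.01, 0.002, 0.003, 0.011)
        times = [10.0, 100.0, 1000.0]
        traj = simulate_photocycle(rates, StateVector.dark(), times)
        a = rates.matrix()
        for i, t in enumerate(times):
            ref = expm(a * t) @ np.array([1.0, 0.0, 0.0])
            assert np.max(np.abs(traj.states[i] - ref)) < 1e-6

    def test_dark_decay_matches_reoxidation_closed_form(self):
        # with k1 = k2 = 0 only reoxidation remains
        start = StateVector(0.3, 0.7, 0.0)
        traj = simulate_photocycle(
            RateConstants(0, 0, 0.005, 0.0), start, [50.0, 400.0]
        )
        params = ReoxidationCurveParams(c_ox=0.3, c_o=0.7, k1b=0.005)
        for i, t in enumerate([50.0, 400.0]):
            ox, rad = reoxidation_decay(params, t)
            assert traj.fad_ox[i] == pytest.approx(ox, abs=1e-6)
            assert traj.fadh_rad[i] == pytest.approx(rad, abs=1e-6)

    @given(k1=rates_st, k2=rates_st, k1b=rates_st, k2b=rates_st)
    @settings(derandomize=True, max_examples=40)
    def test_conservation_and_oracle_equivalence(self, k1, k2, k1b, k2b):
        rates = RateConstants(k1, k2, k1b, k2b)
        times = np.array([1.0, 50.0, 300.0, 2000.0])
        traj = simulate_photocycle(rates, StateVector.dark(), times)
        assert np.max(np.abs(traj.states.sum(axis=1) - 1.0)) < 1e-9
        a = rates.matrix()
        for i, t in enumerate(times):
            ref = expm(a * t) @ np.array([1.0, 0.0, 0.0])
            assert np.max(np.abs(traj.states[i] - ref)) < 1e-6

    def test_rejects_bad_grids(self):
        with pytest.raises(DomainError):
            simulate_photocycle(
                RateConstants(0, 0, 0, 0), StateVector.dark(), [5.0, 1.0]
            )
        with pytest.raises(DomainError):
            simulate_photocycle(
                RateConstants(0, 0, 0, 0), StateVector.dark(), [1.0], step=0.0
            )


class TestTwoState:
    def test_initial_condition(self):
        assert two_state_concentrations(0.37, 0.01, 0.0) == (1.0, 0.0)

    def test_irreversible_limit(self):
        ox, rad = two_state_concentrations(0.01, 0.0, 1e7)
        assert rad == pytest.approx(1.0, abs=1e-12)

    def test_against_ode_oracle(self):
        # brute-force integration of the two-state system
        sol = solve_ivp(
            lambda t, y: [-0.002 * y[0] + 0.003 * y[1],
                          0.002 * y[0] - 0.003 * y[1]],
            (0, 200), [1.0, 0.0], rtol=1e-11, atol=1e-12,
        )
        ox, rad = two_state_concentrations(0.002, 0.003, 200.0)
        assert rad == pytest.approx(sol.y[1, -1], abs=1e-8)
        assert rad == pytest.approx(0.4 * (1 - math.exp(-1)), abs=1e-12)

    @given(k1=st.floats(1e-5, 0.1), k1b=rates_st,
           t1=st.floats(0, 500), t2=st.floats(0, 500))
    @settings(derandomize=True, max_examples=100)
    def test_radical_nondecreasing_in_time_and_k1(self, k1, k1b, t1, t2):
        lo, hi = sorted([t1, t2])
        assert (
            two_state_concentrations(k1, k1b, hi)[1]
            >= two_state_concentrations(k1, k1b, lo)[1]
        )
        assert (
            two_state_concentrations(k1 * 2, k1b, hi)[1]
            >= two_state_concentrations(k1, k1b, hi)[1]
        )

    def test_rejects_negative_time(self):
        with pytest.raises(DomainError):
            two_state_concentrations(0.01, 0.003, -1.0)


class TestReoxidation:
    def test_initial_and_asymptotic_values(self):
        params = ReoxidationCurveParams(c_ox=0.2, c_o=0.8, k1b=0.01)
        assert reoxidation_decay(params, 0.0) == (0.2, 0.8)
        ox, rad = reoxidation_decay(params, 1e7)
        assert (ox, rad) == pytest.approx((1.0, 0.0), abs=1e-12)

    def test_half_life_point(self):
        # k1b = 0.003 1/s halves the radical in 231 s
        params = ReoxidationCurveParams(c_ox=0.0, c_o=1.0, k1b=0.003)
        assert reoxidation_decay(params, 231.0)[1] == pytest.approx(0.5, abs=1e-3)

    @given(c_o=st.floats(0, 1), k1b=st.floats(0, 0.1), td=st.floats(0, 5000))
    @settings(derandomize=True, max_examples=100)
    def test_species_sum_invariant(self, c_o, k1b, td):
        params = ReoxidationCurveParams(c_ox=1 - c_o, c_o=c_o, k1b=k1b)
        ox, rad = reoxidation_decay(params, td)
        assert ox + rad == pytest.approx(1.0, abs=1e-12)


class TestHalfLife:
    @pytest.mark.parametrize(
        "k, expected_rounded", [(0.003, 231), (0.013, 53), (math.log(2), 1)]
    )
    def test_printed_values(self, k, expected_rounded):
        assert round(half_life(k)) == expected_rounded

    @given(k=st.floats(1e-6, 10))
    @settings(derandomize=True, max_examples=50)
    def test_product_identity(self, k):
        assert half_life(k) * k == pytest.approx(math.log(2), rel=1e-15)

    def test_rejects_nonpositive(self):
        with pytest.raises(DomainError):
            half_life(0.0)


class TestSteadyState:
    def test_dark_resting_state(self):
        assert steady_state(RateConstants(0, 0, 0.003, 0.011)) == StateVector.dark()

    def test_symmetric_two_state(self):
        ss = steady_state(RateConstants(0.003, 0, 0.003, 0))
        assert ss.fadh_rad == pytest.approx(0.5, abs=1e-12)

    def test_zeroes_the_derivative(self):
        rates = RateConstants(0.01, 0.002, 0.003, 0.011)
        ss = steady_state(rates)
        assert max(abs(d) for d in photocycle_derivative(ss, rates)) < 1e-12

    def test_matches_long_time_integration(self):
        rates = RateConstants(0.01, 0.002, 0.003, 0.011)
        traj = simulate_photocycle(rates, StateVector.dark(), [1e4])
        assert np.max(np.abs(traj.states[-1] - steady_state(rates).as_array())) < 1e-6

    def test_degenerate_configurations_raise(self):
        with pytest.raises(DomainError):
            steady_state(RateConstants(0, 0, 0, 0))
        with pytest.raises(DomainError):
            steady_state(RateConstants(0.01, 0, 0, 0))  # absorbing radical
        with pytest.raises(DomainError):
            steady_state(RateConstants(0.01, 0.002, 0.003, 0))  # absorbing FADH-
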