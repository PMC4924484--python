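"""Inverse problems: reoxidation fitting, rate inversion, cross sections."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crykinetics.exceptions import DataError, DomainError, InversionError
from crykinetics.estimation import (
    CrossSectionResult,
    DoseResponseSeries,
    ReoxidationFitResult,
    Species,
    Transition,
    average_condition_summary,
    fit_cross_section,
    fit_reoxidation,
    infer_k1,
    infer_k1_steady_state,
    infer_k2,
    infer_k2_steady_state,
    quantum_yield,
    sigma_from_phi,
)
from crykinetics.kinetics import (
    RateConstants,
    ReoxidationCurveParams,
    StateVector,
    reoxidation_decay,
    simulate_photocycle,
    steady_state,
    two_state_concentrations,
)


class TestFitReoxidation:
    def test_noiseless_round_trip_is_exact(self):
        td = np.linspace(0, 600, 10)
        params = ReoxidationCurveParams(c_ox=0.0, c_o=1.0, k1b=0.005)
        _, rad = reoxidation_decay(params, td)
        res = fit_reoxidation(td, rad, Species.FADH_RAD)
        assert res.k1b == pytest.approx(0.005, abs=1e-8)
        assert res.c_o == pytest.approx(1.0, abs=1e-8)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)
        assert res.half_life == pytest.approx(math.log(2) / 0.005, rel=1e-6)

    def test_fadox_recovery_round_trip(self):
        td = np.linspace(0, 900, 12)
        params = ReoxidationCurveParams(c_ox=0.3, c_o=0.7, k1b=0.003)
        ox, _ = reoxidation_decay(params, td)
        res = fit_reoxidation(td, ox, Species.FAD_OX)
        assert res.k1b == pytest.approx(0.003, abs=1e-8)
        assert res.c_ox == pytest.approx(0.3, abs=1e-6)
        assert res.c_o == pytest.approx(0.7, abs=1e-6)

    def test_constant_data_gives_zero_rate(self):
        td = np.linspace(0, 600, 8)
        with pytest.warns(UserWarning, match="constant"):
            res = fit_reoxidation(td, np.full(8, 0.6), Species.FADH_RAD)
        assert res.k1b == 0.0
        assert math.isinf(res.half_life)

    def test_monte_carlo_recovery_under_noise(self):
        # 1% absorbance noise -> sd 0.02 on [FADH.] = 2 A(560)
        errs = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            tau = math.log(2) / 0.003
            td = np.linspace(0, 3 * tau, 20)
            _, rad = reoxidation_decay(
                ReoxidationCurveParams(c_ox=0.3, c_o=0.7, k1b=0.003), td
            )
            noisy = rad + rng.normal(0, 0.02, rad.shape)
            res = fit_reoxidation(td, noisy, Species.FADH_RAD)
            errs.append(abs(res.k1b - 0.003) / 0.003)
        assert np.median(errs) < 0.05

    def test_needs_three_points(self):
        with pytest.raises(DataError):
            fit_reoxidation([0, 10], [1.0, 0.9], Species.FADH_RAD)


class TestInferK1:
    def test_zero_observation_means_no_photoreduction(self):
        assert infer_k1(0.0, Species.FADH_RAD, 20.0, 0.003) == 0.0

    def test_closed_form_when_reoxidation_negligible(self):
        assert infer_k1(0.5, Species.FADH_RAD, 20.0, 0.0) == pytest.approx(
            math.log(2) / 20.0, rel=1e-12
        )

    @pytest.mark.parametrize("species", [Species.FADH_RAD, Species.FAD_OX])
    def test_forward_inverse_round_trip(self, species):
        ox, rad = two_state_concentrations(0.01, 0.003, 20.0)
        obs = rad if species is Species.FADH_RAD else ox
        assert infer_k1(obs, species, 20.0, 0.003) == pytest.approx(0.01, rel=1e-8)

    @given(
        c1=st.floats(0.01, 0.9), c2=st.floats(0.01, 0.9),
        k1b=st.floats(0, 0.02), t=st.floats(1, 100),
    )
    @settings(derandomize=True, max_examples=60)
    def test_strictly_increasing_in_observation(self, c1, c2, k1b, t):
        lo, hi = sorted([c1, c2])
        if hi - lo < 1e-6:
            return
        assert infer_k1(hi, Species.FADH_RAD, t, k1b) > infer_k1(
            lo, Species.FADH_RAD, t, k1b
        )

    def test_steady_state_inversion_identity(self):
        h = 0.4
        k1 = infer_k1_steady_state(h, 0.0023)
        ss = steady_state(RateConstants(k1, 0.0, 0.0023, 0.0))
        assert ss.fadh_rad == pytest.approx(h, rel=1e-12)

    def test_unattainable_observation_raises(self):
        with pytest.raises(DomainError):
            infer_k1(1.0, Species.FADH_RAD, 20.0, 0.003)
        with pytest.raises(InversionError):
            infer_k1_steady_state(1.0, 0.0023)


class TestInferK2:
    def test_two_state_prediction_maps_to_zero(self):
        h0 = two_state_concentrations(0.016, 0.003, 20.0)[1]
        assert infer_k2(h0, 20.0, 0.016, k1b=0.003, k2b=0.011) == pytest.approx(
            0.0, abs=1e-10
        )

    @pytest.mark.parametrize("k1b, k2b", [(0.0, 0.0), (0.003, 0.011)])
    def test_forward_inverse_round_trip(self, k1b, k2b):
        rates = RateConstants(0.016, 0.008, k1b, k2b)
        traj = simulate_photocycle(rates, StateVector.dark(), [20.0])
        k2 = infer_k2(float(traj.fadh_rad[-1]), 20.0, 0.016, k1b=k1b, k2b=k2b)
        assert k2 == pytest.approx(0.008, rel=1e-8)

    def test_observation_above_ceiling_raises(self):
        h0 = two_state_concentrations(0.016, 0.003, 20.0)[1]
        with pytest.raises(InversionError):
            infer_k2(h0 + 0.05, 20.0, 0.016, k1b=0.003, k2b=0.011)

    def test_steady_state_closed_form_identity(self):
        rates = RateConstants(0.01, 0.004, 0.003, 0.011)
        h = steady_state(rates).fadh_rad
        assert infer_k2_steady_state(h, 0.01, 0.003, 0.011) == pytest.approx(
            0.004, rel=1e-10
        )


class TestCrossSection:
    def test_exact_proportionality(self):
        series = DoseResponseSeries(
            np.array([10.0, 100.0, 400.0]), 1.6e-4 * np.array([10.0, 100.0, 400.0])
        )
        fit = fit_cross_section(series)
        assert fit.sigma == pytest.approx(1.6e-4, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_single_point_estimate(self):
        fit = fit_cross_section(DoseResponseSeries(np.array([100.0]), np.array([0.016])))
        assert fit.sigma == pytest.approx(1.6e-4, rel=1e-12)
        assert math.isnan(fit.r_squared)

    def test_monte_carlo_recovery_under_noise(self):
        fluences = np.array([25.0, 50.0, 100.0, 200.0, 400.0, 800.0])
        errs = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            k = 2.5e-4 * fluences * (1 + rng.normal(0, 0.05, fluences.shape))
            fit = fit_cross_section(DoseResponseSeries(fluences, k))
            errs.append(abs(fit.sigma - 2.5e-4) / 2.5e-4)
        assert np.median(errs) < 0.05

    def test_all_zero_fluence_is_unidentifiable(self):
        from crykinetics.exceptions import FitError

        with pytest.raises(FitError):
            fit_cross_section(DoseResponseSeries(np.array([0.0]), np.array([0.0])))


class TestQuantumYield:
    @pytest.mark.parametrize(
        "sigma, eps, expected",
        [
            (1.6e-4, 509.4, 0.137),  # cry2 pH 7.5
            (6.4e-5, 641.55, 0.043),  # cry1 in DTT
            (0.0, 509.4, 0.0),
        ],
    )
    def test_printed_values(self, sigma, eps, expected):
        assert round(quantum_yield(sigma, eps), 3) == pytest.approx(expected)

    @given(phi=st.floats(0, 1), eps=st.floats(100, 1000))
    @settings(derandomize=True, max_examples=50)
    def test_sigma_phi_round_trip(self, phi, eps):
        assert quantum_yield(sigma_from_phi(phi, eps), eps) == pytest.approx(
            phi, abs=1e-12
        )

    def test_above_unity_warns(self):
        with pytest.warns(UserWarning, match="> 1"):
            quantum_yield(2e-3, 509.4)

    def test_rejects_bad_epsilon(self):
        with pytest.raises(DomainError):
            quantum_yield(1e-4, 0.0)


def _xsr(phi, eps, condition, transition=Transition.OX_TO_RADICAL):
    sigma = sigma_from_phi(phi, eps)
    return CrossSectionResult(
        sigma=sigma, phi=quantum_yield(sigma, eps), epsilon=eps,
        r_squared=0.99, transition=transition, condition=condition,
    )


class TestConditionSummary:
    def test_quantum_yield_pair_average(self):
        # the radical-based and oxidized-based estimates for one condition
        row = average_condition_summary(
            _xsr(0.137, 509.4, "cry2 pH 7.5"), _xsr(0.24, 509.4, "cry2 pH 7.5")
        )
        assert round(row["phi"], 2) == 0.19

    def test_half_life_pair_average(self):
        a = ReoxidationFitResult(
            k1b=math.log(2) / 231, c_o=1, c_ox=0, half_life=231.0,
            r_squared=0.996, species_fitted=Species.FADH_RAD, condition="c",
        )
        b = ReoxidationFitResult(
            k1b=math.log(2) / 192, c_o=1, c_ox=0, half_life=192.0,
            r_squared=0.99, species_fitted=Species.FAD_OX, condition="c",
        )
        assert average_condition_summary(a, b)["tau_half_s"] == pytest.approx(211.5)

    def test_idempotent_on_identical_pair(self):
        r = _xsr(0.137, 509.4, "x")
        assert average_condition_summary(r, r)["phi"] == pytest.approx(r.phi)

    def test_mismatched_conditions_raise(self):
        with pytest.raises(DataError):
            average_condition_summary(_xsr(0.1, 509.4, "a"), _xsr(0.1, 509.4, "b"))
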