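"""Inverse computations: rate-constant recovery and quantum-yield estimation.

Three inverse problems are solved here.

* Dark reoxidation: nonlinear least-squares (Levenberg-Marquardt) fit of the
  exponential recovery closed forms to a dark time course, giving k1b and the
  half-life ln(2)/k1b.
* Photoreduction rates: given an observed end-of-illumination concentration,
  the unique forward rate reproducing it is found by bracketed root-finding
  (the predicted concentration is monotone in the rate).  k1 inverts the
  two-state closed form; k2 inverts full three-state forward simulations.
* Photoconversion cross sections: the light-driven rate is proportional to
  photon fluence rate, k = sigma * I, so sigma comes from a through-origin
  least-squares fit of rate versus fluence, and the quantum yield follows
  from sigma = 2.3 * eps * phi.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from lmfit import Model
from scipy.optimize import brentq

from .exceptions import DataError, DomainError, FitError, InversionError
from .kinetics import (
    DEFAULT_STEP,
    RateConstants,
    StateVector,
    half_life,
    simulate_photocycle,
    two_state_concentrations,
)

__all__ = [
    "Species",
    "Transition",
    "ReoxidationFitResult",
    "DoseResponseSeries",
    "CrossSectionResult",
    "CrossSectionFit",
    "fit_reoxidation",
    "infer_k1",
    "infer_k1_steady_state",
    "infer_k2",
    "infer_k2_steady_state",
    "fit_cross_section",
    "quantum_yield",
    "sigma_from_phi",
    "cross_section_result",
    "average_condition_summary",
]

#: Rate below which a fitted decay is reported as "no decay".
_ZERO_RATE = 1e-14

#: Absolute root-finding tolerance on rate constants (1/s).
_ROOT_XTOL = 1e-14


class Species(str, enum.Enum):
    """Which redox species a concentration observation refers to."""

    FADH_RAD = "fadh_rad"
    FAD_OX = "fad_ox"


class Transition(str, enum.Enum):
    """Which photoreduction step a cross section describes."""

    OX_TO_RADICAL = "ox_to_radical"
    RADICAL_TO_REDUCED = "radical_to_reduced"


@dataclass(frozen=True)
class ReoxidationFitResult:
    """Output of a dark-reoxidation exponential fit."""

    k1b: float
    c_o: float
    c_ox: float
    half_life: float
    r_squared: float
    species_fitted: Species
    n_points: int = 0
    condition: str = ""


@dataclass(frozen=True)
class DoseResponseSeries:
    """Paired photon fluence rates and responses (rates or concentrations)."""

    fluence: np.ndarray
    response: np.ndarray
    response_kind: str = "k1"
    illumination_time: float = 0.0

    def __post_init__(self) -> None:
        fl = np.asarray(self.fluence, dtype=float)
        resp = np.asarray(self.response, dtype=float)
        object.__setattr__(self, "fluence", fl)
        object.__setattr__(self, "response", resp)
        if fl.ndim != 1 or resp.shape != fl.shape:
            raise DataError("fluence and response must be 1-D, same length")
        if np.any(fl < 0):
            raise DataError("fluence rates must be >= 0")
        if np.unique(fl).size != fl.size:
            raise DataError("fluence rates must be distinct")
        if self.response_kind not in ("k1", "k2", "fadh_rad", "readout"):
            raise DataError(f"unknown response_kind {self.response_kind!r}")


@dataclass(frozen=True)
class CrossSectionResult:
    """Fitted photoconversion cross section and derived quantum yield.

    ``sigma`` is in umol^-1 m^2 (fluence rates in umol m^-2 s^-1), ``epsilon``
    in mol^-1 m^2; the unit bridge sigma[mol^-1 m^2] = 1e6 * sigma[umol^-1 m^2]
    is applied inside :func:`quantum_yield` only.
    """

    sigma: float
    phi: float
    epsilon: float
    r_squared: float
    transition: Transition
    n_points: int = 0
    species_fitted: Species = Species.FADH_RAD
    condition: str = ""

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise DomainError("sigma must be >= 0")
        expected_phi = quantum_yield(self.sigma, self.epsilon)
        if not math.isclose(self.phi, expected_phi, rel_tol=1e-9, abs_tol=1e-12):
            raise DomainError(
                f"phi = {self.phi} inconsistent with sigma/(2.3 eps) = {expected_phi}"
            )


class CrossSectionFit(NamedTuple):
    """Raw through-origin fit of rate versus fluence."""

    sigma: float
    r_squared: float
    n_points: int


def _fadh_decay(td, c_o, k1b):
    return c_o * np.exp(-k1b * td)


def _fadox_recovery(td, c_ox, c_o, k1b):
    return c_ox + c_o * (1.0 - np.exp(-k1b * td))


def _decay_rate_init(td: np.ndarray, decaying: np.ndarray) -> float:
    """Log-linear initial guess for the decay rate from the positive part."""
    mask = decaying > 0
    if mask.sum() >= 2:
        slope = np.polyfit(td[mask], np.log(decaying[mask]), 1)[0]
        if slope < 0:
            return float(-slope)
    return 1e-3


def fit_reoxidation(
    td, conc, species: Species | str = Species.FADH_RAD, condition: str = ""
) -> ReoxidationFitResult:
    """Fit the dark-recovery time course of one species to find k1b.

    ``species`` selects the model: exponential decay for FADH. or the
    complementary recovery for FADox.  Constant data yield k1b = 0 with a
    warning.  R^2 is 1 - SS_res/SS_tot with the centered total sum of squares.
    """
    species = Species(species)
    td = np.asarray(td, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if td.ndim != 1 or conc.shape != td.shape:
        raise DataError("td and conc must be 1-D, same length")
    if td.size < 3:
        raise DataError("reoxidation fit needs at least 3 points")
    if np.any(td < 0) or np.any(np.diff(td) <= 0):
        raise DataError("td must be increasing and >= 0")

    if np.ptp(conc) < 1e-12:
        warnings.warn(
            "constant concentration series: reporting k1b = 0 (no decay)",
            stacklevel=2,
        )
        c_level = float(conc[0])
        c_o = c_level if species is Species.FADH_RAD else 0.0
        c_ox = c_level if species is Species.FAD_OX else 0.0
        return ReoxidationFitResult(
            k1b=0.0, c_o=c_o, c_ox=c_ox, half_life=math.inf, r_squared=1.0,
            species_fitted=species, n_points=td.size, condition=condition,
        )

    if species is Species.FADH_RAD:
        model = Model(_fadh_decay)
        params = model.make_params(
            c_o=dict(value=max(float(conc[0]), 1e-6), min=0.0, max=1.5),
            k1b=dict(value=_decay_rate_init(td, conc), min=0.0),
        )
    else:
        plateau = float(conc[-1])
        model = Model(_fadox_recovery)
        params = model.make_params(
            c_ox=dict(value=max(float(conc[0]), 0.0), min=0.0, max=1.5),
            c_o=dict(value=max(plateau - float(conc[0]), 1e-6), min=0.0, max=1.5),
            k1b=dict(value=_decay_rate_init(td, plateau - conc), min=0.0),
        )

    result = model.fit(conc, params, td=td, method="leastsq")
    if not result.success:
        raise FitError(f"reoxidation fit did not converge: {result.message}")

    k1b = float(result.params["k1b"].value)
    c_o = float(result.params["c_o"].value)
    c_ox = float(result.params["c_ox"].value) if species is Species.FAD_OX else (
        1.0 - c_o if c_o <= 1.0 else 0.0
    )
    ss_res = float(np.sum(result.residual**2))
    ss_tot = float(np.sum((conc - conc.mean()) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    tau = half_life(k1b) if k1b > _ZERO_RATE else math.inf
    return ReoxidationFitResult(
        k1b=k1b, c_o=c_o, c_ox=c_ox, half_life=tau, r_squared=r_squared,
        species_fitted=species, n_points=td.size, condition=condition,
    )


def _bracketed_root(objective, description: str) -> float:
    """Root of a monotone objective on [0, inf): doubling bracket + Brent.

    ``objective`` must be >= 0 at k = 0 and eventually negative.
    """
    f0 = objective(0.0)
    if f0 < 0:
        raise InversionError(f"{description}: observation unattainable at rate 0")
    if f0 == 0:
        return 0.0
    k_hi = 1.0
    while objective(k_hi) > 0:
        k_hi *= 2.0
        if k_hi > 1e9:
            raise InversionError(
                f"{description}: no rate below 1e9 1/s reproduces the observation"
            )
    return float(brentq(objective, 0.0, k_hi, xtol=_ROOT_XTOL, rtol=1e-15))


def infer_k1(
    conc_obs: float,
    species: Species | str,
    t_illum: float,
    k1b: float,
) -> float:
    """Invert the two-state model for the photoreduction rate k1.

    Finds the unique k1 >= 0 such that the two-state solution at ``t_illum``
    reproduces the observed concentration of the chosen species.  With
    k1b = 0 (illumination much shorter than reoxidation) the closed form
    k1 = -ln(1 - [FADH.])/t applies directly.
    """
    species = Species(species)
    if not (t_illum > 0):
        raise DomainError("t_illum must be > 0")
    if k1b < 0:
        raise DomainError("k1b must be >= 0")
    h_obs = conc_obs if species is Species.FADH_RAD else 1.0 - conc_obs
    if not (0.0 <= h_obs < 1.0):
        raise DomainError(
            f"observed concentration implies [FADH.] = {h_obs}, outside [0, 1)"
        )
    if h_obs == 0.0:
        return 0.0
    if k1b == 0.0:
        return -math.log1p(-h_obs) / t_illum

    def objective(k1: float) -> float:
        return h_obs - two_state_concentrations(k1, k1b, t_illum)[1]

    # objective(0) = h_obs > 0 and predicted FADH. is increasing in k1.
    return _bracketed_root(objective, "infer_k1")


def infer_k1_steady_state(fadh_obs: float, k1b: float) -> float:
    """Invert the two-state steady state H = k1/(k1+k1b) for k1.

    Used for readouts integrated over times much longer than the
    reoxidation half-life (continuous-growth experiments).
    """
    if not (k1b > 0):
        raise DomainError("steady-state inversion requires k1b > 0")
    if not (0.0 <= fadh_obs < 1.0):
        raise InversionError(
            f"steady-state [FADH.] = {fadh_obs} unattainable (must be in [0, 1))"
        )
    return k1b * fadh_obs / (1.0 - fadh_obs)


def infer_k2(
    fadh_obs: float,
    t_illum: float,
    k1: float,
    k1b: float = 0.0,
    k2b: float = 0.0,
    step: float = DEFAULT_STEP,
) -> float:
    """Invert three-state forward simulations for the green-light rate k2.

    Finds the unique k2 >= 0 such that integrating the full photocycle from
    the dark state for ``t_illum`` yields the observed [FADH.].  Green light
    only depletes the radical, so the prediction is decreasing in k2 and the
    observation must not exceed the k2 = 0 prediction.  Passing
    k1b = k2b = 0 gives the reduced short-illumination mode.
    """
    if not (t_illum > 0):
        raise DomainError("t_illum must be > 0")
    if not (0.0 <= fadh_obs <= 1.0):
        raise DomainError(f"[FADH.] observation {fadh_obs} outside [0, 1]")

    def predict(k2: float) -> float:
        rates = RateConstants(k1=k1, k2=k2, k1b=k1b, k2b=k2b)
        traj = simulate_photocycle(rates, StateVector.dark(), [t_illum], step=step)
        return float(traj.fadh_rad[-1])

    h0 = predict(0.0)
    if fadh_obs > h0 + 1e-9:
        raise InversionError(
            f"[FADH.] = {fadh_obs} exceeds the k2 = 0 prediction {h0:.6g}: "
            "data inconsistent with green-light depletion"
        )
    fadh_obs = min(fadh_obs, h0)  # absorb float-level overshoot

    def objective(k2: float) -> float:
        return predict(k2) - fadh_obs

    # objective(0) = h0 - obs >= 0 and the prediction is decreasing in k2.
    return _bracketed_root(objective, "infer_k2")


def infer_k2_steady_state(
    fadh_obs: float, k1: float, k1b: float, k2b: float
) -> float:
    """Closed-form steady-state inversion for k2.

    At steady state H = 1 / (1 + (k2+k1b)/k1 + k2/k2b); solving for k2 is
    linear.  The observation must not exceed the k2 = 0 plateau k1/(k1+k1b).
    """
    if not (k1 > 0 and k1b > 0 and k2b > 0):
        raise DomainError("steady-state inversion requires k1, k1b, k2b > 0")
    if not (0.0 < fadh_obs <= 1.0):
        raise InversionError(f"steady-state [FADH.] = {fadh_obs} outside (0, 1]")
    h0 = k1 / (k1 + k1b)
    if fadh_obs > h0 + 1e-12:
        raise InversionError(
            f"[FADH.] = {fadh_obs} exceeds the k2 = 0 steady state {h0:.6g}"
        )
    k2 = (1.0 / fadh_obs - 1.0 - k1b / k1) / (1.0 / k1 + 1.0 / k2b)
    return max(k2, 0.0)


def fit_cross_section(series: DoseResponseSeries) -> CrossSectionFit:
    """Through-origin least squares of rate constant versus fluence rate.

    k = sigma * I has no intercept (no light, no photoreduction), so
    sigma = sum(I k) / sum(I^2) and R^2 uses the uncentered total sum of
    squares.  A single-point series is permitted (R^2 undefined, NaN).
    """
    if series.response_kind not in ("k1", "k2"):
        raise DataError(
            f"cross-section fit needs rate constants, got {series.response_kind!r}"
        )
    fluence, rate = series.fluence, series.response
    if fluence.size < 1:
        raise DataError("cross-section fit needs at least one point")
    denom = float(np.sum(fluence**2))
    if denom == 0.0:
        raise FitError("all fluence rates are zero: sigma is unidentifiable")
    sigma = float(np.sum(fluence * rate) / denom)
    nonzero = fluence > 0
    if nonzero.sum() < 2:
        r_squared = math.nan
    else:
        ss_res = float(np.sum((rate - sigma * fluence) ** 2))
        ss_tot = float(np.sum(rate**2))
        r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return CrossSectionFit(sigma=sigma, r_squared=r_squared, n_points=fluence.size)


def quantum_yield(sigma: float, epsilon: float) -> float:
    """Quantum yield from cross section: phi = sigma / (2.3 eps).

    ``sigma`` is per umol (umol^-1 m^2, matching fluence rates in
    umol m^-2 s^-1) while ``epsilon`` is per mol (mol^-1 m^2), so sigma is
    scaled by 1e6 here -- the only place the unit bridge is applied.
    """
    if not (epsilon > 0):
        raise DomainError(f"epsilon must be > 0, got {epsilon!r}")
    if sigma < 0:
        raise DomainError(f"sigma must be >= 0, got {sigma!r}")
    phi = sigma * 1e6 / (2.3 * epsilon)
    if phi > 1.0:
        warnings.warn(
            f"quantum yield {phi:.3g} > 1: signal amplification or wrong epsilon?",
            stacklevel=2,
        )
    return phi


def sigma_from_phi(phi: float, epsilon: float) -> float:
    """Inverse of :func:`quantum_yield`: sigma (umol^-1 m^2) from phi."""
    if not (epsilon > 0):
        raise DomainError(f"epsilon must be > 0, got {epsilon!r}")
    return 2.3 * epsilon * phi * 1e-6


def cross_section_result(
    fit: CrossSectionFit,
    epsilon: float,
    transition: Transition | str,
    species_fitted: Species | str = Species.FADH_RAD,
    condition: str = "",
) -> CrossSectionResult:
    """Package a raw sigma fit with its derived quantum yield."""
    return CrossSectionResult(
        sigma=fit.sigma,
        phi=quantum_yield(fit.sigma, epsilon),
        epsilon=epsilon,
        r_squared=fit.r_squared,
        transition=Transition(transition),
        n_points=fit.n_points,
        species_fitted=Species(species_fitted),
        condition=condition,
    )


def average_condition_summary(
    result_a: ReoxidationFitResult | CrossSectionResult,
    result_b: ReoxidationFitResult | CrossSectionResult,
) -> dict:
    """Average the FADox-based and FADH.-based estimates for one condition.

    Returns one summary-table row: the arithmetic mean of the half-life for
    reoxidation fits, or of sigma (reported in mol^-1 m^2) and phi for
    cross-section fits, alongside both member values.
    """
    if result_a.condition != result_b.condition:
        raise DataError(
            f"condition labels differ: {result_a.condition!r} vs {result_b.condition!r}"
        )
    if type(result_a) is not type(result_b):
        raise DataError("cannot average results of different kinds")
    row: dict = {"condition": result_a.condition}
    if isinstance(result_a, ReoxidationFitResult):
        row["tau_half_s"] = (result_a.half_life + result_b.half_life) / 2.0
        row["tau_half_members_s"] = (result_a.half_life, result_b.half_life)
        row["k1b_members"] = (result_a.k1b, result_b.k1b)
    else:
        if result_a.transition is not result_b.transition:
            raise DataError("cannot average cross sections of different transitions")
        sigma = (result_a.sigma + result_b.sigma) / 2.0
        row["transition"] = result_a.transition.value
        row["sigma_mol_m2"] = sigma * 1e6
        row["phi"] = (result_a.phi + result_b.phi) / 2.0
        row["sigma_members_umol_m2"] = (result_a.sigma, result_b.sigma)
        row["phi_members"] = (result_a.phi, result_b.phi)
    row["r_squared_members"] = (result_a.r_squared, result_b.r_squared)
    return row
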