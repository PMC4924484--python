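"""Quantum-yield estimation from whole-seedling biological readouts.

The flavin redox state cannot be measured inside living plants, so a
biological response serves as a proxy: blue-light inhibition of hypocotyl
elongation for cry1, and blue-light-induced degradation of the cry2 protein
for cry2 (both assayed in phytochrome-deficient seedlings).  The signaling
(FADH.) concentration is taken as inversely proportional to the readout,
realized here as the affine map anchored at the dark readout (no FADH.) and
the saturating readout (full conversion).  The resulting fluence-to-FADH.
curve is then inverted exactly as for in vitro spectra: per fluence a
forward rate, a through-origin cross-section fit, and a quantum yield
computed with the receptor's in vitro extinction coefficient.

Two exposure modes are supported: ``steady_state`` for readouts integrated
over days of growth (t >> reoxidation half-life), where the two-state steady
state H = k1/(k1+k1b) applies, and ``finite_t`` for timed treatments such as
the 30-min cry2 degradation assay, where the finite-time solution is
inverted instead.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .exceptions import DataError, DomainError, InversionError
from .estimation import (
    CrossSectionResult,
    DoseResponseSeries,
    Species,
    Transition,
    cross_section_result,
    fit_cross_section,
    infer_k1,
    infer_k1_steady_state,
    infer_k2,
    infer_k2_steady_state,
)
from .kinetics import two_state_concentrations

__all__ = [
    "ReadoutKind",
    "ExposureMode",
    "BioReadoutSeries",
    "LiteratureRates",
    "readout_to_fadh",
    "invivo_blue_quantum_yield",
    "invivo_green_quantum_yield",
    "DEFAULT_FINITE_T",
]

#: Default timed-exposure duration (s): the 30-min degradation assay.
DEFAULT_FINITE_T = 1800.0


class ReadoutKind(str, enum.Enum):
    HYPOCOTYL_LENGTH = "hypocotyl_length"
    PROTEIN_LEVEL = "protein_level"


class ExposureMode(str, enum.Enum):
    STEADY_STATE = "steady_state"
    FINITE_T = "finite_t"


@dataclass(frozen=True)
class BioReadoutSeries:
    """Dose-response table of fluence rate versus biological readout."""

    fluence: np.ndarray
    readout: np.ndarray
    stderr: np.ndarray
    readout_kind: ReadoutKind
    receptor: str
    co_fluence_blue: float = 0.0

    def __post_init__(self) -> None:
        fl = np.asarray(self.fluence, dtype=float)
        ro = np.asarray(self.readout, dtype=float)
        se = np.asarray(self.stderr, dtype=float)
        object.__setattr__(self, "fluence", fl)
        object.__setattr__(self, "readout", ro)
        object.__setattr__(self, "stderr", se)
        object.__setattr__(self, "readout_kind", ReadoutKind(self.readout_kind))
        if fl.ndim != 1 or ro.shape != fl.shape or se.shape != fl.shape:
            raise DataError("fluence, readout and stderr must be 1-D, same length")
        if np.any(fl < 0):
            raise DataError("fluence rates must be >= 0")
        if np.any(ro <= 0):
            raise DataError("readouts must be > 0")
        if self.receptor.lower() not in ("cry1", "cry2"):
            raise DataError(f"unknown receptor {self.receptor!r}")
        if self.co_fluence_blue < 0:
            raise DataError("co_fluence_blue must be >= 0")


@dataclass(frozen=True)
class LiteratureRates:
    """Light-independent rates taken from in vivo flavin-lifetime studies.

    Defaults: k1b = 0.0023 1/s (cry1), 7.2e-4 1/s (cry2), k2b = 0.011 1/s.
    """

    k1b_cry1_invivo: float = 0.0023
    k1b_cry2_invivo: float = 7.2e-4
    k2b: float = 0.011

    def k1b_for(self, receptor: str) -> float:
        table = {"cry1": self.k1b_cry1_invivo, "cry2": self.k1b_cry2_invivo}
        try:
            return table[receptor.lower()]
        except KeyError:
            raise DomainError(f"unknown receptor {receptor!r}") from None


def default_anchors(series: BioReadoutSeries) -> tuple[float, float]:
    """(dark, saturated) anchors when none are given: max and min readout.

    The highest observed readout stands in for the dark level and the
    lowest for saturation.  This is only an approximation -- it pins the
    extreme observed points to H = 0 and H = 1 exactly -- so calibrated
    anchors should be passed whenever available.
    """
    return float(series.readout.max()), float(series.readout.min())


def readout_to_fadh(
    series: BioReadoutSeries,
    readout_dark: float,
    readout_saturated: float,
) -> np.ndarray:
    """Affine, order-reversing map from readout to normalized [FADH.].

    H(I) = (dark - readout(I)) / (dark - saturated), clamped to [0, 1].
    The dark anchor is the readout with no signaling state formed; the
    saturated anchor corresponds to complete conversion (H = 1).
    """
    span = readout_dark - readout_saturated
    if span == 0:
        raise DataError("degenerate calibration: dark and saturated readouts equal")
    h = (readout_dark - series.readout) / span
    return np.clip(h, 0.0, 1.0)


def _resolve_anchors(
    series: BioReadoutSeries,
    readout_dark: float | None,
    readout_saturated: float | None,
) -> tuple[float, float]:
    d_default, s_default = default_anchors(series)
    return (
        d_default if readout_dark is None else readout_dark,
        s_default if readout_saturated is None else readout_saturated,
    )


def invivo_blue_quantum_yield(
    series: BioReadoutSeries,
    rates: LiteratureRates,
    eps: float,
    exposure_mode: ExposureMode | str = ExposureMode.STEADY_STATE,
    t_illum: float = DEFAULT_FINITE_T,
    readout_dark: float | None = None,
    readout_saturated: float | None = None,
) -> CrossSectionResult:
    """Estimate sigma1 and phi1 from a blue-light dose-response series.

    Per fluence rate, k1 is recovered from the FADH. proxy (steady-state
    closed form or finite-time two-state inversion), then sigma1 from the
    through-origin fit k1 = sigma1 * I1 and phi1 from the receptor's in
    vitro extinction coefficient ``eps`` (mol^-1 m^2).
    """
    if series.fluence.size < 2:
        raise DataError("need at least 2 fluence rates")
    mode = ExposureMode(exposure_mode)
    k1b = rates.k1b_for(series.receptor)
    dark, saturated = _resolve_anchors(series, readout_dark, readout_saturated)
    h = readout_to_fadh(series, dark, saturated)

    k1_values = np.empty_like(h)
    for i, h_i in enumerate(h):
        if mode is ExposureMode.STEADY_STATE:
            if h_i >= 1.0:
                raise InversionError(
                    f"H = 1 at fluence {series.fluence[i]:g}: unattainable at steady "
                    "state; provide a saturated anchor outside the observed range"
                )
            k1_values[i] = infer_k1_steady_state(h_i, k1b)
        else:
            h_i = min(h_i, 1.0 - 1e-12)
            k1_values[i] = infer_k1(h_i, Species.FADH_RAD, t_illum, k1b)

    fit = fit_cross_section(
        DoseResponseSeries(series.fluence, k1_values, "k1", t_illum)
    )
    return cross_section_result(
        fit, eps, Transition.OX_TO_RADICAL,
        species_fitted=Species.FADH_RAD, condition=series.receptor,
    )


def invivo_green_quantum_yield(
    series: BioReadoutSeries,
    k1: float,
    rates: LiteratureRates,
    eps2: float,
    exposure_mode: ExposureMode | str = ExposureMode.FINITE_T,
    t_illum: float = DEFAULT_FINITE_T,
    readout_dark: float | None = None,
    readout_saturated: float | None = None,
    neglect_reoxidation: bool = False,
) -> CrossSectionResult:
    """Estimate sigma2 and phi2 from a green-light co-illumination series.

    The series holds green fluence rates under a fixed blue co-illumination
    (``series.co_fluence_blue`` > 0); ``k1`` is the blue-light rate found in
    the blue-only experiments.  Per green fluence, k2 is recovered by the
    three-state inversion; noisy points marginally above the k2 = 0
    prediction are censored to k2 = 0.  ``eps2`` is the radical extinction
    eps_ox(450)/2 in mol^-1 m^2.
    """
    if series.co_fluence_blue <= 0:
        raise DataError("green-series analysis requires co_fluence_blue > 0")
    if series.fluence.size < 2:
        raise DataError("need at least 2 green fluence rates")
    mode = ExposureMode(exposure_mode)
    k1b = 0.0 if neglect_reoxidation else rates.k1b_for(series.receptor)
    k2b = 0.0 if neglect_reoxidation else rates.k2b
    dark, saturated = _resolve_anchors(series, readout_dark, readout_saturated)
    h = readout_to_fadh(series, dark, saturated)

    if h.size >= 3:
        slope = np.polyfit(series.fluence, h, 1)[0] * float(np.ptp(series.fluence))
        if slope > 0.05:  # clear upward trend, beyond noise wiggle
            raise InversionError(
                "[FADH.] increases with green fluence: inconsistent with "
                "green-light depletion of the radical"
            )

    if mode is ExposureMode.STEADY_STATE:
        h0 = k1 / (k1 + k1b) if (k1 + k1b) > 0 else 0.0
    else:
        h0 = two_state_concentrations(k1, k1b, t_illum)[1]

    k2_values = np.empty_like(h)
    for i, h_i in enumerate(h):
        h_i = min(h_i, h0)  # censor noise overshoot above the k2 = 0 prediction
        if mode is ExposureMode.STEADY_STATE:
            k2_values[i] = infer_k2_steady_state(h_i, k1, k1b, k2b)
        else:
            k2_values[i] = infer_k2(h_i, t_illum, k1, k1b, k2b)

    fit = fit_cross_section(
        DoseResponseSeries(series.fluence, k2_values, "k2", t_illum)
    )
    return cross_section_result(
        fit, eps2, Transition.RADICAL_TO_REDUCED,
        species_fitted=Species.FADH_RAD, condition=series.receptor,
    )
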