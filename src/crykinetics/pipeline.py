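"""End-to-end analysis stages: spectra in, rate constants and yields out.

Each function takes a list of :class:`~crykinetics.spectra.SpectrumRecord`
(with a dark_initial reference among them), normalizes to the dark 450-nm
absorbance, converts the 450/560-nm bands to redox-state concentrations,
and runs the appropriate inverse computation.
"""

from __future__ import annotations

import warnings

import numpy as np

from .exceptions import DataError
from .estimation import (
    CrossSectionResult,
    DoseResponseSeries,
    ReoxidationFitResult,
    Species,
    Transition,
    cross_section_result,
    fit_cross_section,
    fit_reoxidation,
    infer_k1,
    infer_k2,
)
from .kinetics import two_state_concentrations
from .spectra import (
    Condition,
    SpectrumRecord,
    absorbance_to_concentrations,
    normalize_to_dark,
)

__all__ = [
    "split_dark_reference",
    "concentration_series",
    "analyze_reoxidation",
    "analyze_blue_dose",
    "analyze_green_dose",
]


def split_dark_reference(
    records: list[SpectrumRecord],
) -> tuple[SpectrumRecord, list[SpectrumRecord]]:
    """Separate the dark_initial reference from the measurement records."""
    darks = [r for r in records if r.condition is Condition.DARK_INITIAL]
    if len(darks) != 1:
        raise DataError(f"expected exactly one dark_initial record, got {len(darks)}")
    rest = [r for r in records if r.condition is not Condition.DARK_INITIAL]
    return darks[0], rest


def concentration_series(records: list[SpectrumRecord], tol: float | None = None):
    """Normalized records -> per-record StateVector via the 450/560 bands."""
    kwargs = {} if tol is None else {"tol": tol}
    states = []
    for rec in records:
        states.append(
            absorbance_to_concentrations(
                rec.absorbance_at(450.0), rec.absorbance_at(560.0),
                label=rec.label, **kwargs,
            )
        )
    return states


def analyze_reoxidation(
    records: list[SpectrumRecord], condition: str = "",
    physicality_tol: float | None = None,
) -> dict[Species, ReoxidationFitResult]:
    """Fit the dark-recovery time course from both species' perspectives.

    Returns the FADH.-decay fit and the FADox-recovery fit; the pair feeds
    :func:`~crykinetics.estimation.average_condition_summary`.
    """
    dark, rest = split_dark_reference(records)
    recovery = [r for r in rest if r.condition is Condition.DARK_RECOVERY]
    if len(recovery) < 3:
        raise DataError("need at least 3 dark-recovery spectra")
    recovery.sort(key=lambda r: r.time)
    normalized = normalize_to_dark(recovery, dark)
    states = concentration_series(normalized, tol=physicality_tol)
    td = np.array([r.time for r in recovery])
    results = {}
    for species, values in (
        (Species.FADH_RAD, np.array([s.fadh_rad for s in states])),
        (Species.FAD_OX, np.array([s.fad_ox for s in states])),
    ):
        results[species] = fit_reoxidation(td, values, species, condition=condition)
    return results


def _invert_blue_record(
    h_obs: float, t_illum: float, k1b: float, label: str
) -> float:
    if h_obs >= 1.0 - 1e-9:
        warnings.warn(
            f"[FADH.] = {h_obs:.4f} at {label}: at the two-state ceiling, "
            "clamping before inversion",
            stacklevel=2,
        )
        h_obs = 1.0 - 1e-9
    return infer_k1(h_obs, Species.FADH_RAD, t_illum, k1b)


def analyze_blue_dose(
    records: list[SpectrumRecord],
    k1b: float,
    eps_ox_450: float,
    t_illum: float | None = None,
    condition: str = "",
    physicality_tol: float | None = None,
) -> dict[Species, CrossSectionResult]:
    """Recover sigma1/phi1 from a blue-light dose series.

    Runs the two-state inversion per fluence rate twice -- once from the
    observed [FADH.] and once from [FADox] -- and fits each rate set
    through the origin, mirroring the dual analysis used to check that the
    two-state model holds.  ``eps_ox_450`` is in mol^-1 m^2.
    """
    dark, rest = split_dark_reference(records)
    lit = [r for r in rest if r.fluence_blue > 0]
    if len(lit) < 1:
        raise DataError("need at least one illuminated spectrum")
    normalized = normalize_to_dark(lit, dark)
    states = concentration_series(normalized, tol=physicality_tol)
    fluences = np.array([r.fluence_blue for r in lit])
    times = {r.time for r in lit}
    if t_illum is None:
        if len(times) != 1:
            raise DataError("records carry differing illumination times; pass t_illum")
        t_illum = times.pop()

    results = {}
    for species in (Species.FADH_RAD, Species.FAD_OX):
        k1_values = []
        for rec, state in zip(lit, states):
            h_obs = state.fadh_rad if species is Species.FADH_RAD else 1.0 - state.fad_ox
            k1_values.append(_invert_blue_record(h_obs, t_illum, k1b, rec.label))
        fit = fit_cross_section(
            DoseResponseSeries(fluences, np.array(k1_values), "k1", t_illum)
        )
        results[species] = cross_section_result(
            fit, eps_ox_450, Transition.OX_TO_RADICAL,
            species_fitted=species, condition=condition,
        )
    return results


def analyze_green_dose(
    records: list[SpectrumRecord],
    k1: float,
    eps_h_560: float,
    k1b: float = 0.0,
    k2b: float = 0.0,
    t_illum: float | None = None,
    condition: str = "",
    physicality_tol: float | None = None,
) -> CrossSectionResult:
    """Recover sigma2/phi2 from a blue/green co-illumination dose series.

    ``k1`` is the blue-light rate from the blue-only stage; passing
    k1b = k2b = 0 selects the reduced short-illumination mode.
    ``eps_h_560`` is the radical extinction eps_ox(450)/2 in mol^-1 m^2.
    """
    dark, rest = split_dark_reference(records)
    lit = [r for r in rest if r.fluence_blue > 0]
    if len(lit) < 2:
        raise DataError("need at least two co-illuminated spectra")
    normalized = normalize_to_dark(lit, dark)
    states = concentration_series(normalized, tol=physicality_tol)
    fluences = np.array([r.fluence_green for r in lit])
    times = {r.time for r in lit}
    if t_illum is None:
        if len(times) != 1:
            raise DataError("records carry differing illumination times; pass t_illum")
        t_illum = times.pop()

    h0 = two_state_concentrations(k1, k1b, t_illum)[1]
    k2_values = []
    for rec, state in zip(lit, states):
        # noise can push [FADH.] marginally above the k2 = 0 ceiling; censor
        h_obs = min(state.fadh_rad, h0)
        k2_values.append(infer_k2(h_obs, t_illum, k1, k1b=k1b, k2b=k2b))
    fit = fit_cross_section(
        DoseResponseSeries(fluences, np.array(k2_values), "k2", t_illum)
    )
    return cross_section_result(
        fit, eps_h_560, Transition.RADICAL_TO_REDUCED,
        species_fitted=Species.FADH_RAD, condition=condition,
    )
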