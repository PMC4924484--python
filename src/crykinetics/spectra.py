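"""Beer-Lambert bridge between absorbance spectra and redox-state concentrations.

Only two of the three flavin redox states absorb in the 400-570 nm window:
FADox absorbs blue (450 nm band) and FADH. absorbs both blue and green
(560 nm band); FADH- absorbs outside this window entirely.  With the
half-extinction assumption eps_H(450) = eps_H(560) = eps_ox(450)/2 and all
absorbances normalized to the dark spectrum at 450 nm, the two measured
bands invert linearly to concentrations:

    [FADox](t)  = A(450, t) - A(560, t)
    [FADH.](t)  = 2 A(560, t)

and [FADH-] follows from conservation of total flavin.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace

import numpy as np

from .exceptions import DataError, DomainError
from .kinetics import StateVector

__all__ = [
    "Condition",
    "ExtinctionSet",
    "SpectrumRecord",
    "CRY1_EPS_OX_450_M_CM",
    "CRY2_EPS_OX_450_M_CM",
    "normalize_to_dark",
    "absorbance_to_concentrations",
    "concentrations_to_absorbance",
    "initial_molar_concentration",
    "convert_epsilon_units",
    "epsilon_to_molar_cm",
]

#: Measured oxidized-flavin extinction coefficients at 450 nm (M^-1 cm^-1).
CRY1_EPS_OX_450_M_CM = 6415.5
CRY2_EPS_OX_450_M_CM = 5094.0

#: Tolerance for physicality checks on derived concentrations: components may
#: stray into [-0.02, 1.02] (measurement noise) before being clamped to [0, 1].
PHYSICALITY_TOL = 0.02

#: Nearest-neighbor window (nm) when reading a band off a wavelength grid.
BAND_LOOKUP_WINDOW_NM = 2.0


class Condition(str, enum.Enum):
    """Illumination condition under which a spectrum was acquired."""

    ILLUMINATED_BLUE = "illuminated_blue"
    ILLUMINATED_BLUE_GREEN = "illuminated_blue_green"
    DARK_RECOVERY = "dark_recovery"
    DARK_INITIAL = "dark_initial"


@dataclass(frozen=True)
class ExtinctionSet:
    """Molar extinction coefficients (mol^-1 m^2) and optical path (cm).

    Internally extinctions are stored in mol^-1 m^2; ``from_molar_cm`` accepts
    the spectroscopist's customary M^-1 cm^-1 (1 M^-1 cm^-1 = 0.1 mol^-1 m^2).
    When ``enforce_half_rule`` is set (the default), the radical extinction is
    required to satisfy eps_H(450) = eps_H(560) = eps_ox(450)/2.
    """

    eps_ox_450: float
    eps_h_450: float
    eps_h_560: float
    path_length: float = 1.0
    enforce_half_rule: bool = True

    def __post_init__(self) -> None:
        for name in ("eps_ox_450", "eps_h_450", "eps_h_560", "path_length"):
            value = getattr(self, name)
            if not (value > 0) or not math.isfinite(value):
                raise DomainError(f"{name} must be finite and > 0, got {value!r}")
        if self.enforce_half_rule:
            half = self.eps_ox_450 / 2.0
            if not (
                math.isclose(self.eps_h_450, half, rel_tol=1e-9)
                and math.isclose(self.eps_h_560, half, rel_tol=1e-9)
            ):
                raise DomainError(
                    "half-extinction assumption violated: expected "
                    f"eps_h_450 = eps_h_560 = {half}, got "
                    f"({self.eps_h_450}, {self.eps_h_560})"
                )

    @classmethod
    def from_molar_cm(
        cls, eps_ox_450_M_cm: float, path_length: float = 1.0
    ) -> "ExtinctionSet":
        """Build the set from eps_ox(450) in M^-1 cm^-1, applying the half rule."""
        eps = convert_epsilon_units(eps_ox_450_M_cm)
        return cls(eps, eps / 2.0, eps / 2.0, path_length=path_length)

    @classmethod
    def for_receptor(cls, receptor: str, path_length: float = 1.0) -> "ExtinctionSet":
        """Extinction set for 'cry1' or 'cry2' from the measured values."""
        table = {"cry1": CRY1_EPS_OX_450_M_CM, "cry2": CRY2_EPS_OX_450_M_CM}
        try:
            return cls.from_molar_cm(table[receptor.lower()], path_length)
        except KeyError:
            raise DomainError(f"unknown receptor {receptor!r}") from None


@dataclass(frozen=True)
class SpectrumRecord:
    """One absorbance spectrum with acquisition time and illumination metadata."""

    wavelengths: np.ndarray
    absorbance: np.ndarray
    time: float
    condition: Condition
    fluence_blue: float = 0.0
    fluence_green: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "absorbance", ab)
        object.__setattr__(self, "condition", Condition(self.condition))
        if wl.ndim != 1 or ab.shape != wl.shape:
            raise DataError("wavelengths and absorbance must be 1-D, same length")
        if np.any(np.diff(wl) <= 0):
            raise DataError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(ab)):
            raise DataError("absorbance values must be finite")
        if self.fluence_blue < 0 or self.fluence_green < 0:
            raise DataError("fluence rates must be >= 0")
        if self.condition in (Condition.DARK_RECOVERY, Condition.DARK_INITIAL) and (
            self.fluence_blue or self.fluence_green
        ):
            raise DataError("dark-condition spectra must have zero fluence rates")

    def absorbance_at(self, wavelength_nm: float) -> float:
        """Absorbance at the grid point nearest ``wavelength_nm`` (within +-2 nm)."""
        idx = int(np.argmin(np.abs(self.wavelengths - wavelength_nm)))
        if abs(self.wavelengths[idx] - wavelength_nm) > BAND_LOOKUP_WINDOW_NM:
            raise DataError(
                f"no grid point within {BAND_LOOKUP_WINDOW_NM} nm of {wavelength_nm} nm"
            )
        return float(self.absorbance[idx])


def normalize_to_dark(
    series: list[SpectrumRecord], dark: SpectrumRecord
) -> list[SpectrumRecord]:
    """Divide every spectrum by the dark record's 450-nm absorbance.

    The dark record itself then has A(450) = 1, which anchors the
    normalized-concentration scale ([FADox] = 1 in darkness).
    """
    if dark.condition is not Condition.DARK_INITIAL:
        raise DataError("dark reference must have condition dark_initial")
    a450 = dark.absorbance_at(450.0)
    if a450 <= 0:
        raise DataError(f"dark A(450) must be > 0, got {a450}")
    return [replace(rec, absorbance=rec.absorbance / a450) for rec in series]


def absorbance_to_concentrations(
    a450: float, a560: float, label: str = "", tol: float = PHYSICALITY_TOL
) -> StateVector:
    """Invert normalized band absorbances to redox-state concentrations.

    FADH- never enters through absorbance (it does not absorb in-window);
    it is always computed by conservation.  Components may exceed [0, 1] by
    up to ``tol`` (noise; widen it for noisier instruments) and are then
    clamped and renormalized; grosser violations raise ``DataError``.
    """
    ox = a450 - a560
    rad = 2.0 * a560
    minus = 1.0 - ox - rad
    where = f" in spectrum {label!r}" if label else ""
    for name, value in (("FADox", ox), ("FADH_rad", rad), ("FADH_minus", minus)):
        if value < -tol or value > 1.0 + tol:
            raise DataError(
                f"derived [{name}] = {value:.4f}{where} outside "
                f"[-{tol}, 1 + {tol}]"
            )
    comps = np.clip([ox, rad, minus], 0.0, 1.0)
    total = comps.sum()
    if total <= 0:
        raise DataError(f"all derived concentrations are zero{where}")
    return StateVector.from_array(comps / total)


def concentrations_to_absorbance(state: StateVector) -> tuple[float, float]:
    """Forward Beer-Lambert map to normalized band absorbances.

    Under the half-extinction assumption A(450) = [FADox] + [FADH.]/2 and
    A(560) = [FADH.]/2; composing with ``absorbance_to_concentrations`` is
    the identity on ([FADox], [FADH.]).
    """
    a560 = state.fadh_rad / 2.0
    a450 = state.fad_ox + a560
    return (a450, a560)


def initial_molar_concentration(a450_dark: float, eps: ExtinctionSet) -> float:
    """Molar protein concentration from the dark 450-nm absorbance.

    In darkness all flavin is oxidized, so A(450, 0) = eps_ox(450) c d with
    eps in M^-1 cm^-1 and d the path length in cm.  Returns mol/L.
    """
    if not (a450_dark > 0):
        raise DataError(f"dark A(450) must be > 0, got {a450_dark!r}")
    eps_molar_cm = epsilon_to_molar_cm(eps.eps_ox_450)
    return a450_dark / (eps_molar_cm * eps.path_length)


def convert_epsilon_units(eps_M_cm: float) -> float:
    """Convert an extinction coefficient from M^-1 cm^-1 to mol^-1 m^2.

    1 M^-1 cm^-1 = 0.1 mol^-1 m^2.
    """
    if not (eps_M_cm > 0):
        raise DomainError(f"extinction must be > 0, got {eps_M_cm!r}")
    return eps_M_cm / 10.0


def epsilon_to_molar_cm(eps_mol_m2: float) -> float:
    """Inverse of :func:`convert_epsilon_units` (mol^-1 m^2 to M^-1 cm^-1)."""
    if not (eps_mol_m2 > 0):
        raise DomainError(f"extinction must be > 0, got {eps_mol_m2!r}")
    return eps_mol_m2 * 10.0
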