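"""Synthetic photocycle data with known ground truth.

Generates every input kind the analysis stages consume: photoreduction and
dark-recovery absorbance spectra, blue- and green-light dose series, and in
vivo biological-readout series, all produced by the same kinetic model the
estimators invert, with additive Gaussian instrument noise on absorbance
(multiplicative on biological readouts) and a deterministic seed.

The per-species extinction curves are smooth Gaussian stand-ins, not
literature flavin spectra: the spectral inversion uses only the 450- and
560-nm band values, so only the constraints that matter there are enforced
exactly -- eps_ox(450) equals the configured value, eps_ox(560) = 0,
eps_H(450) = eps_H(560) = eps_ox(450)/2, and FADH- does not absorb in the
400-570 nm window at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DomainError
from .invivo import (
    DEFAULT_FINITE_T,
    BioReadoutSeries,
    ExposureMode,
    LiteratureRates,
    ReadoutKind,
)
from .kinetics import (
    RateConstants,
    ReoxidationCurveParams,
    StateVector,
    half_life,
    reoxidation_decay,
    simulate_photocycle,
    two_state_concentrations,
)
from .spectra import Condition, ExtinctionSet, SpectrumRecord

__all__ = [
    "SyntheticConfig",
    "synth_basis_spectra",
    "generate_reoxidation_series",
    "generate_blue_dose_series",
    "generate_green_dose_series",
    "generate_invivo_readouts",
]

_OX_WIDTH_NM = 30.0  # Gaussian width of the oxidized-flavin blue band
_H_CENTER_NM = 505.0  # radical band center: midpoint of 450 and 560 nm
_H_WIDTH_NM = 60.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth parameters and experiment design for data generation.

    Defaults reproduce the flagship in vitro condition (cry2 at pH 7.5):
    sigma1 = 1.6e-4 umol^-1 m^2, sigma2 = 1.6e-5 umol^-1 m^2, k1b = 0.003 1/s,
    k2b = 0.011 1/s, 20-s illuminations, blue fluences in the linear range
    25-400 umol m^-2 s^-1 and green fluences 0-1000 umol m^-2 s^-1.
    ``noise_sd`` is the additive Gaussian absorbance noise in units of the
    normalized dark A(450) (0.01 = 1% of the dark absorbance).
    """

    sigma1_true: float = 1.6e-4
    sigma2_true: float = 1.6e-5
    k1b_true: float = 0.003
    k2b_true: float = 0.011
    eps: ExtinctionSet = field(
        default_factory=lambda: ExtinctionSet.from_molar_cm(5094.0)
    )
    noise_sd: float = 0.0
    seed: int = 0
    wavelengths: np.ndarray = field(
        default_factory=lambda: np.arange(400.0, 572.0, 2.0)
    )
    t_illum: float = 20.0
    blue_fluences: tuple = (25.0, 50.0, 100.0, 200.0, 400.0)
    green_fluences: tuple = (0.0, 50.0, 100.0, 200.0, 400.0, 700.0, 1000.0)
    reox_fluence: float = 200.0
    reox_times: tuple | None = None
    #: Raw dark absorbance at 450 nm (AU); spectra are emitted on this raw
    #: scale so that the analysis side exercises dark normalization.
    dark_a450: float = 0.5094
    # --- in vivo design ---
    invivo_rates: LiteratureRates = field(default_factory=LiteratureRates)
    readout_dark: float = 1.0
    readout_saturated: float = 0.2
    readout_noise_frac: float = 0.0
    cry1_fluences: tuple = (0.1, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 80.0, 100.0)
    cry2_fluences: tuple = (0.1, 0.25, 0.5, 1.0, 2.0, 5.0, 10.0)
    invivo_green_fluences: tuple = (0.0, 10.0, 25.0, 50.0, 100.0, 250.0, 500.0)
    invivo_blue_co_fluence: float = 10.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.readout_noise_frac < 0:
            raise DomainError("noise levels must be >= 0")
        object.__setattr__(
            self, "wavelengths", np.asarray(self.wavelengths, dtype=float)
        )

    @property
    def rates_true(self) -> RateConstants:
        """Light-independent truth; forward rates follow from sigma * I."""
        return RateConstants(0.0, 0.0, self.k1b_true, self.k2b_true)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def reox_time_grid(self) -> np.ndarray:
        """Dark sampling grid: 12 points over 3.5 half-lives by default."""
        if self.reox_times is not None:
            return np.asarray(self.reox_times, dtype=float)
        tau = half_life(self.k1b_true)
        return np.linspace(0.0, 3.5 * tau, 12)


def synth_basis_spectra(
    wavelengths: Sequence[float], eps_ox_450: float = 509.4
) -> dict[str, np.ndarray]:
    """Per-species extinction curves (mol^-1 m^2) on the given grid.

    The oxidized band is a tail-subtracted Gaussian, exactly zero at 560 nm;
    the radical band is a Gaussian centered midway between 450 and 560 nm,
    hence exactly equal at both and scaled to eps_ox(450)/2.  The fully
    reduced species does not absorb in this window.
    """
    wl = np.asarray(wavelengths, dtype=float)
    if np.any(wl < 400.0) or np.any(wl > 570.0):
        raise DomainError("wavelength grid must lie within 400-570 nm")
    g = np.exp(-((wl - 450.0) ** 2) / (2.0 * _OX_WIDTH_NM**2))
    g450 = 1.0
    g560 = math.exp(-((560.0 - 450.0) ** 2) / (2.0 * _OX_WIDTH_NM**2))
    eps_ox = eps_ox_450 * np.clip((g - g560) / (g450 - g560), 0.0, None)
    offset = (450.0 - _H_CENTER_NM) ** 2
    eps_h = (eps_ox_450 / 2.0) * np.exp(
        -(((wl - _H_CENTER_NM) ** 2) - offset) / (2.0 * _H_WIDTH_NM**2)
    )
    return {
        "wavelengths": wl,
        "fad_ox": eps_ox,
        "fadh_rad": eps_h,
        "fadh_minus": np.zeros_like(wl),
    }


def _render_spectrum(
    config: SyntheticConfig,
    basis: dict[str, np.ndarray],
    state,
    time: float,
    condition: Condition,
    rng: np.random.Generator,
    fluence_blue: float = 0.0,
    fluence_green: float = 0.0,
    label: str = "",
) -> SpectrumRecord:
    ox, rad = state[0], state[1]
    a_norm = (basis["fad_ox"] * ox + basis["fadh_rad"] * rad) / config.eps.eps_ox_450
    if config.noise_sd > 0:
        a_norm = a_norm + rng.normal(0.0, config.noise_sd, size=a_norm.shape)
    return SpectrumRecord(
        wavelengths=basis["wavelengths"],
        absorbance=config.dark_a450 * a_norm,
        time=time,
        condition=condition,
        fluence_blue=fluence_blue,
        fluence_green=fluence_green,
        label=label,
    )


def _dark_record(
    config: SyntheticConfig, basis: dict[str, np.ndarray], rng: np.random.Generator
) -> SpectrumRecord:
    return _render_spectrum(
        config, basis, (1.0, 0.0, 0.0), 0.0, Condition.DARK_INITIAL, rng,
        label="dark",
    )


def generate_reoxidation_series(
    config: SyntheticConfig,
    illumination: tuple[float, float] | None = None,
) -> tuple[list[SpectrumRecord], dict]:
    """Photoreduce, then follow the dark recovery spectroscopically.

    ``illumination`` is (blue fluence rate, duration s); defaults to the
    configured reoxidation experiment (200 umol m^-2 s^-1 for 20 s).  The
    first record is the pre-illumination dark spectrum; the rest sample the
    dark time course.  Returns the records and a ground-truth sidecar.
    """
    fluence, duration = illumination or (config.reox_fluence, config.t_illum)
    rng = config.rng()
    basis = synth_basis_spectra(config.wavelengths, config.eps.eps_ox_450)
    k1 = config.sigma1_true * fluence
    c_ox, c_o = two_state_concentrations(k1, config.k1b_true, duration)
    params = ReoxidationCurveParams(c_ox=c_ox, c_o=c_o, k1b=config.k1b_true)
    td = config.reox_time_grid()
    ox_t, rad_t = reoxidation_decay(params, td)

    records = [_dark_record(config, basis, rng)]
    for t, ox, rad in zip(td, ox_t, rad_t):
        records.append(
            _render_spectrum(
                config, basis, (ox, rad), float(t), Condition.DARK_RECOVERY, rng,
                label=f"td={t:g}s",
            )
        )
    truth = {
        "k1b_true": config.k1b_true,
        "k1_during_illumination": k1,
        "c_ox": float(c_ox),
        "c_o": float(c_o),
        "illumination_fluence": fluence,
        "illumination_time": duration,
        "noise_sd": config.noise_sd,
        "seed": config.seed,
    }
    return records, truth


def generate_blue_dose_series(
    config: SyntheticConfig,
) -> tuple[list[SpectrumRecord], pd.DataFrame, dict]:
    """End-of-illumination spectra at each blue fluence rate.

    Per fluence I1, k1 = sigma1_true * I1 and the two-state photocycle
    (k2 = 0 under monochromatic blue) is run for the illumination time.
    Returns records (dark reference first), the design table, and the
    ground-truth sidecar.
    """
    rng = config.rng()
    basis = synth_basis_spectra(config.wavelengths, config.eps.eps_ox_450)
    records = [_dark_record(config, basis, rng)]
    rows = []
    for fluence in config.blue_fluences:
        k1 = config.sigma1_true * fluence
        ox, rad = two_state_concentrations(k1, config.k1b_true, config.t_illum)
        records.append(
            _render_spectrum(
                config, basis, (ox, rad), config.t_illum,
                Condition.ILLUMINATED_BLUE, rng,
                fluence_blue=fluence, label=f"I1={fluence:g}",
            )
        )
        rows.append({"fluence_blue": fluence, "k1_true": k1,
                     "fad_ox_true": ox, "fadh_rad_true": rad})
    design = pd.DataFrame(rows)
    truth = {
        "sigma1_true": config.sigma1_true,
        "k1b_true": config.k1b_true,
        "illumination_time": config.t_illum,
        "noise_sd": config.noise_sd,
        "seed": config.seed,
    }
    return records, design, truth


def generate_green_dose_series(
    config: SyntheticConfig,
    blue_fluence: float = 100.0,
) -> tuple[list[SpectrumRecord], pd.DataFrame, dict]:
    """Blue/green co-illumination spectra at each green fluence rate.

    k1 = sigma1_true * I1 is fixed by the blue co-illumination; per green
    fluence I2, k2 = sigma2_true * I2 and the full three-state photocycle
    (including reoxidation) is integrated for the illumination time.
    """
    rng = config.rng()
    basis = synth_basis_spectra(config.wavelengths, config.eps.eps_ox_450)
    k1 = config.sigma1_true * blue_fluence
    records = [_dark_record(config, basis, rng)]
    rows = []
    for fluence in config.green_fluences:
        k2 = config.sigma2_true * fluence
        rates = RateConstants(k1, k2, config.k1b_true, config.k2b_true)
        traj = simulate_photocycle(rates, StateVector.dark(), [config.t_illum])
        state = traj.states[-1]
        condition = (
            Condition.ILLUMINATED_BLUE if fluence == 0
            else Condition.ILLUMINATED_BLUE_GREEN
        )
        records.append(
            _render_spectrum(
                config, basis, state, config.t_illum, condition, rng,
                fluence_blue=blue_fluence, fluence_green=fluence,
                label=f"I2={fluence:g}",
            )
        )
        rows.append({
            "fluence_green": fluence, "k2_true": k2,
            "fad_ox_true": state[0], "fadh_rad_true": state[1],
            "fadh_minus_true": state[2],
        })
    design = pd.DataFrame(rows)
    truth = {
        "sigma1_true": config.sigma1_true,
        "sigma2_true": config.sigma2_true,
        "k1_true": k1,
        "k1b_true": config.k1b_true,
        "k2b_true": config.k2b_true,
        "blue_fluence": blue_fluence,
        "illumination_time": config.t_illum,
        "noise_sd": config.noise_sd,
        "seed": config.seed,
    }
    return records, design, truth


def generate_invivo_readouts(
    config: SyntheticConfig,
    receptor: str = "cry2",
    readout_kind: ReadoutKind | str = ReadoutKind.PROTEIN_LEVEL,
    exposure_mode: ExposureMode | str = ExposureMode.FINITE_T,
    channel: str = "blue",
    t_illum: float = DEFAULT_FINITE_T,
) -> tuple[BioReadoutSeries, dict]:
    """Biological dose-response readouts from the generating kinetics.

    ``channel='blue'`` varies the blue fluence rate (hypocotyl or
    degradation assays); ``channel='green'`` varies green under the fixed
    blue co-illumination ``config.invivo_blue_co_fluence``.  The FADH.
    concentration per fluence (steady-state or finite-time kinetics with
    the in vivo literature reoxidation rates) is mapped through the inverse
    affine readout map and multiplicative Gaussian noise is added; the
    stderr column carries the noise scale.
    """
    readout_kind = ReadoutKind(readout_kind)
    mode = ExposureMode(exposure_mode)
    if channel not in ("blue", "green"):
        raise DomainError(f"channel must be 'blue' or 'green', got {channel!r}")
    rng = config.rng()
    k1b = config.invivo_rates.k1b_for(receptor)
    k2b = config.invivo_rates.k2b

    if channel == "blue":
        fluences = np.asarray(
            config.cry1_fluences if receptor.lower() == "cry1"
            else config.cry2_fluences,
            dtype=float,
        )
        h = np.empty_like(fluences)
        for i, fl in enumerate(fluences):
            k1 = config.sigma1_true * fl
            if mode is ExposureMode.STEADY_STATE:
                h[i] = k1 / (k1 + k1b) if (k1 + k1b) > 0 else 0.0
            else:
                h[i] = two_state_concentrations(k1, k1b, t_illum)[1]
        co_blue = 0.0
        k1_fixed = None
    else:
        fluences = np.asarray(config.invivo_green_fluences, dtype=float)
        co_blue = config.invivo_blue_co_fluence
        k1_fixed = config.sigma1_true * co_blue
        h = np.empty_like(fluences)
        for i, fl in enumerate(fluences):
            k2 = config.sigma2_true * fl
            rates = RateConstants(k1_fixed, k2, k1b, k2b)
            if mode is ExposureMode.STEADY_STATE:
                from .kinetics import steady_state

                h[i] = steady_state(rates).fadh_rad
            else:
                traj = simulate_photocycle(rates, StateVector.dark(), [t_illum])
                h[i] = float(traj.fadh_rad[-1])

    span = config.readout_dark - config.readout_saturated
    readout_clean = config.readout_dark - h * span
    if config.readout_noise_frac > 0:
        noise = rng.normal(0.0, config.readout_noise_frac, size=readout_clean.shape)
        readout = readout_clean * (1.0 + noise)
        readout = np.maximum(readout, 1e-6)
    else:
        readout = readout_clean.copy()
    stderr = config.readout_noise_frac * readout_clean

    series = BioReadoutSeries(
        fluence=fluences,
        readout=readout,
        stderr=stderr,
        readout_kind=readout_kind,
        receptor=receptor,
        co_fluence_blue=co_blue,
    )
    truth = {
        "sigma1_true": config.sigma1_true,
        "sigma2_true": config.sigma2_true,
        "k1b": k1b,
        "k2b": k2b,
        "k1_fixed": k1_fixed,
        "fadh_true": h.tolist(),
        "readout_dark": config.readout_dark,
        "readout_saturated": config.readout_saturated,
        "exposure_mode": mode.value,
        "t_illum": t_illum,
        "channel": channel,
        "noise_frac": config.readout_noise_frac,
        "seed": config.seed,
    }
    return series, truth
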