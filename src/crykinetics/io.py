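"""File round-tripping: spectra CSVs, readout CSVs, sidecars and reports.

Spectra travel as wide delimited text -- first column ``wavelength_nm``,
one column per spectrum -- with a YAML sidecar holding per-column metadata
(acquisition time, condition, fluence rates).  Numeric round trips are
bit-exact: floats are written with ``repr`` precision.  A long dialect
(``wavelength_nm,column,absorbance``) is read transparently.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import DataError
from .invivo import BioReadoutSeries, ReadoutKind
from .spectra import Condition, SpectrumRecord

__all__ = [
    "write_spectra",
    "read_spectra",
    "write_readouts",
    "read_readouts",
    "write_truth",
    "read_truth",
    "write_report",
]

_FLOAT_FMT = "%.17g"


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".meta.yaml")


def _column_name(rec: SpectrumRecord, used: set[str]) -> str:
    base = f"t={rec.time:g}"
    name = base
    i = 1
    while name in used:
        i += 1
        name = f"{base}#{i}"
    used.add(name)
    return name


def write_spectra(
    records: list[SpectrumRecord],
    csv_path: str | Path,
    meta_path: str | Path | None = None,
    metadata: dict | None = None,
) -> Path:
    """Write a spectrum series as wide CSV plus a YAML metadata sidecar."""
    if not records:
        raise DataError("no records to write")
    csv_path = Path(csv_path)
    meta_path = Path(meta_path) if meta_path else _sidecar_path(csv_path)
    wl = records[0].wavelengths
    for rec in records[1:]:
        if not np.array_equal(rec.wavelengths, wl):
            raise DataError("all records in one file must share a wavelength grid")

    used: set[str] = set()
    columns: dict[str, np.ndarray] = {"wavelength_nm": wl}
    column_meta = []
    for rec in records:
        name = _column_name(rec, used)
        columns[name] = rec.absorbance
        column_meta.append(
            {
                "column": name,
                "time_s": float(rec.time),
                "condition": rec.condition.value,
                "fluence_blue_umol_m2_s": float(rec.fluence_blue),
                "fluence_green_umol_m2_s": float(rec.fluence_green),
                "label": rec.label,
            }
        )
    pd.DataFrame(columns).to_csv(csv_path, index=False, float_format=_FLOAT_FMT)
    meta = dict(metadata or {})
    meta["columns"] = column_meta
    meta_path.write_text(yaml.safe_dump(meta, sort_keys=False))
    return csv_path


def read_spectra(
    csv_path: str | Path, meta_path: str | Path | None = None
) -> tuple[list[SpectrumRecord], dict]:
    """Read a spectrum series (wide or long CSV) and its metadata sidecar."""
    csv_path = Path(csv_path)
    meta_path = Path(meta_path) if meta_path else _sidecar_path(csv_path)
    if not csv_path.exists():
        raise FileNotFoundError(csv_path)
    if not meta_path.exists():
        raise FileNotFoundError(meta_path)
    meta = yaml.safe_load(meta_path.read_text())
    frame = pd.read_csv(csv_path, float_precision="round_trip")
    if "wavelength_nm" not in frame.columns:
        raise DataError(f"{csv_path}: missing wavelength_nm column")

    if set(frame.columns) >= {"wavelength_nm", "column", "absorbance"}:
        # long dialect: pivot back to wide
        frame = frame.pivot(
            index="wavelength_nm", columns="column", values="absorbance"
        ).reset_index()

    wl = frame["wavelength_nm"].to_numpy(dtype=float)
    records = []
    for cm in meta.get("columns", []):
        name = cm["column"]
        if name not in frame.columns:
            raise DataError(f"{csv_path}: sidecar references missing column {name!r}")
        records.append(
            SpectrumRecord(
                wavelengths=wl,
                absorbance=frame[name].to_numpy(dtype=float),
                time=float(cm["time_s"]),
                condition=Condition(cm["condition"]),
                fluence_blue=float(cm.get("fluence_blue_umol_m2_s", 0.0)),
                fluence_green=float(cm.get("fluence_green_umol_m2_s", 0.0)),
                label=str(cm.get("label", "")),
            )
        )
    return records, meta


def write_readouts(
    series: BioReadoutSeries,
    csv_path: str | Path,
    meta_path: str | Path | None = None,
    metadata: dict | None = None,
) -> Path:
    """Write a biological dose-response series as CSV plus YAML sidecar."""
    csv_path = Path(csv_path)
    meta_path = Path(meta_path) if meta_path else _sidecar_path(csv_path)
    pd.DataFrame(
        {
            "fluence_umol_m2_s": series.fluence,
            "readout": series.readout,
            "stderr": series.stderr,
        }
    ).to_csv(csv_path, index=False, float_format=_FLOAT_FMT)
    meta = dict(metadata or {})
    meta.update(
        {
            "readout_kind": series.readout_kind.value,
            "receptor": series.receptor,
            "co_fluence_blue_umol_m2_s": float(series.co_fluence_blue),
        }
    )
    meta_path.write_text(yaml.safe_dump(meta, sort_keys=False))
    return csv_path


def read_readouts(
    csv_path: str | Path, meta_path: str | Path | None = None
) -> tuple[BioReadoutSeries, dict]:
    csv_path = Path(csv_path)
    meta_path = Path(meta_path) if meta_path else _sidecar_path(csv_path)
    if not csv_path.exists():
        raise FileNotFoundError(csv_path)
    if not meta_path.exists():
        raise FileNotFoundError(meta_path)
    meta = yaml.safe_load(meta_path.read_text())
    frame = pd.read_csv(csv_path, float_precision="round_trip")
    series = BioReadoutSeries(
        fluence=frame["fluence_umol_m2_s"].to_numpy(dtype=float),
        readout=frame["readout"].to_numpy(dtype=float),
        stderr=frame["stderr"].to_numpy(dtype=float),
        readout_kind=ReadoutKind(meta["readout_kind"]),
        receptor=str(meta["receptor"]),
        co_fluence_blue=float(meta.get("co_fluence_blue_umol_m2_s", 0.0)),
    )
    return series, meta


def write_truth(truth: dict, path: str | Path) -> Path:
    """Ground-truth sidecar for synthetic data (YAML)."""
    path = Path(path)
    path.write_text(yaml.safe_dump(truth, sort_keys=False))
    return path


def read_truth(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def _rounded(row: dict) -> dict:
    """Display-rounded companion values: phi to 3 significant figures,
    half-lives to whole seconds."""
    out = {}
    for key, value in row.items():
        if key.startswith("phi") and isinstance(value, float) and value > 0:
            out[key + "_display"] = float(f"{value:.3g}")
        if key.startswith("tau") and isinstance(value, float) and math.isfinite(value):
            out[key + "_display"] = round(value)
    return out


def write_report(
    rows: list[dict], csv_path: str | Path, json_path: str | Path | None = None
) -> Path:
    """Summary-table report: one row per condition, CSV plus JSON.

    Columns follow the condition/half-life/cross-section/quantum-yield
    layout (tau_half_s, sigma1_mol_m2, sigma2_mol_m2, phi1, phi2) with
    whatever per-fit diagnostics the rows carry.
    """
    if not rows:
        raise DataError("no report rows")
    rows = [{**row, **_rounded(row)} for row in rows]
    frame = pd.DataFrame(rows)
    csv_path = Path(csv_path)
    frame.to_csv(csv_path, index=False, float_format=_FLOAT_FMT)
    if json_path is not None:
        Path(json_path).write_text(json.dumps(rows, indent=2, default=str))
    return csv_path
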