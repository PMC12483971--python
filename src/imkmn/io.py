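"""Readers and writers for the package's file dialects.

* Spectrum files: two columns (y [keV/um], f(y)), whitespace or comma
  separated, ``#`` comments, optional header line; a dose-weighted d(y)
  column is accepted behind an explicit flag and converted via
  f(y) proportional to d(y)/y.
* Dose-response CSV: columns ``dose_Gy, value, sd, endpoint, quality_label,
  schedule_label`` (``sd`` and the label columns optional).
* Parameter files: JSON or YAML with keys alpha0, beta0, a_plus_c, r_d, h.
* Schedule CSV: columns ``start_h, duration_h, doserate_Gy_per_h``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core_model import CellParameters, IrradiationSchedule
from .inference import DataError, DoseResponseDataset
from .microdosimetry import InvalidSpectrumError, MicrodosimetricSpectrum

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "read_dose_response",
    "write_dose_response",
    "read_cell_parameters",
    "write_cell_parameters",
    "read_schedule",
    "write_schedule",
    "ParseError",
]


class ParseError(ValueError):
    """Raised for malformed input files, with the offending line where known."""


def read_spectrum(path, dose_weighted: bool = False, meta: str = "") -> MicrodosimetricSpectrum:
    """Parse a two-column lineal-energy spectrum file.

    ``dose_weighted=True`` declares the second column to be d(y); it is then
    converted to a frequency density before renormalisation.
    """
    path = Path(path)
    ys: list[float] = []
    fs: list[float] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 2:
            raise ParseError(f"{path}:{lineno}: expected two columns, got {len(parts)}")
        try:
            y, f = float(parts[0]), float(parts[1])
        except ValueError:
            if not ys:  # tolerate a single textual header line
                continue
            raise ParseError(f"{path}:{lineno}: non-numeric row {line!r}") from None
        ys.append(y)
        fs.append(f)
    if len(ys) < 1:
        raise ParseError(f"{path}: no data rows")
    y_arr, f_arr = np.asarray(ys), np.asarray(fs)
    try:
        if dose_weighted:
            return MicrodosimetricSpectrum.from_dose_weighted(y_arr, f_arr, meta=meta or path.stem)
        return MicrodosimetricSpectrum(y_arr, f_arr, meta=meta or path.stem)
    except InvalidSpectrumError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_spectrum(spectrum: MicrodosimetricSpectrum, path) -> None:
    path = Path(path)
    lines = [f"# lineal-energy spectrum: {spectrum.meta}", "# y_keV_um f_y"]
    for y, f in zip(spectrum.y_grid, spectrum.density):
        lines.append(f"{y:.10e} {f:.10e}")
    path.write_text("\n".join(lines) + "\n")


def read_dose_response(path, endpoint: str | None = None) -> DoseResponseDataset:
    """Read a dose-response CSV into a dataset, validating invariants."""
    path = Path(path)
    df = pd.read_csv(path)
    cols = {c.strip(): c for c in df.columns}
    if "dose_Gy" not in cols or "value" not in cols:
        raise ParseError(f"{path}: need columns 'dose_Gy' and 'value'")
    endpoint_kind = endpoint
    if endpoint_kind is None:
        if "endpoint" in cols:
            kinds = set(df[cols["endpoint"]].astype(str).str.strip())
            if len(kinds) != 1:
                raise ParseError(f"{path}: mixed endpoint kinds {sorted(kinds)}")
            endpoint_kind = kinds.pop()
        else:
            endpoint_kind = "survival"
    sd = None
    if "sd" in cols and df[cols["sd"]].notna().any():
        sd = df[cols["sd"]].to_numpy(dtype=float)
    label = ""
    if "quality_label" in cols and len(df):
        label = str(df[cols["quality_label"]].iloc[0])
    try:
        return DoseResponseDataset(
            doses=df[cols["dose_Gy"]].to_numpy(dtype=float),
            values=df[cols["value"]].to_numpy(dtype=float),
            sd=sd,
            endpoint_kind=endpoint_kind,
            label=label or path.stem,
        )
    except DataError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_dose_response(dataset: DoseResponseDataset, path) -> None:
    df = pd.DataFrame(
        {
            "dose_Gy": dataset.doses,
            "value": dataset.values,
            "sd": dataset.sd if dataset.sd is not None else np.nan,
            "endpoint": dataset.endpoint_kind,
            "quality_label": dataset.quality.label,
            "schedule_label": dataset.schedule.label if dataset.schedule else "acute",
        }
    )
    df.to_csv(path, index=False)


def read_cell_parameters(path) -> CellParameters:
    """Load a cell-line parameter set from JSON or YAML."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ParseError(f"{path}: expected a mapping of parameter names")
    try:
        return CellParameters(
            alpha0=float(data["alpha0"]),
            beta0=float(data["beta0"]),
            a_plus_c=float(data.get("a_plus_c", 2.19)),
            r_d=float(data.get("r_d", 0.42)),
            h_mn=float(data.get("h", data.get("h_mn", 0.275))),
            label=str(data.get("label", path.stem)),
        )
    except KeyError as exc:
        raise ParseError(f"{path}: missing required key {exc}") from exc


def write_cell_parameters(params: CellParameters, path) -> None:
    path = Path(path)
    data = {
        "alpha0": params.alpha0,
        "beta0": params.beta0,
        "a_plus_c": params.a_plus_c,
        "r_d": params.r_d,
        "h": params.h_mn,
        "label": params.label,
    }
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def read_schedule(path, label: str = "") -> IrradiationSchedule:
    """Read a piecewise-constant schedule CSV (start_h, duration_h, doserate_Gy_per_h)."""
    path = Path(path)
    df = pd.read_csv(path)
    needed = ("start_h", "duration_h", "doserate_Gy_per_h")
    for col in needed:
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    segments = [
        (float(r.start_h), float(r.duration_h), float(r.doserate_Gy_per_h))
        for r in df.itertuples()
    ]
    return IrradiationSchedule(segments, label=label or path.stem)


def write_schedule(schedule: IrradiationSchedule, path) -> None:
    df = pd.DataFrame(schedule.segments, columns=["start_h", "duration_h", "doserate_Gy_per_h"])
    df.to_csv(path, index=False)
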