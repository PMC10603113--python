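"""Plain-text I/O: time-series CSV and flat key-value parameter files.

CSV dialect is fixed (comma separator, UTF-8, ``.`` decimal, one header
row, optional leading ``#`` comment lines) rather than sniffed, so runs
are reproducible byte for byte.  Numeric values are written with 17
significant digits, which round-trips IEEE doubles exactly.

Parameter files mirror the model's conventional symbol names — growth
blocks E..I and Fe-rate blocks J..N, suffixed _S (reducer) and _R
(oxidizer) — so a reader can cross-check a file against the printed
equations directly.  Within each block the letters map to: amplitude
(E/J), late denominator (F/K), early denominator (G/L), half-time (H/M),
exponent (I/N).
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import CalibrationFit, LinearCalibration
from .errors import ConfigError, TimeSeriesFormatError
from .lan import LanParameters, RateBlock
from .timeseries import TIME_COLUMN, TimeSeries

_FLOAT_FMT = "%.17g"

_BLOCK_LETTERS = {
    "growth_S": ("E_S", "F_S", "G_S", "H_S", "I_S"),
    "growth_R": ("E_R", "F_R", "G_R", "H_R", "I_R"),
    "ferate_S": ("J_S", "K_S", "L_S", "M_S", "N_S"),
    "ferate_R": ("J_R", "K_R", "L_R", "M_R", "N_R"),
}
_SCALARS = ("fe_total", "cells_S0", "cells_R0", "fe2_0")


def write_timeseries(ts: TimeSeries, path, header_comment: str | None = None) -> None:
    """Write a time series as CSV, optionally with a ``#`` comment header."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        ts.data.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_timeseries(path) -> TimeSeries:
    """Read a time-series CSV written by :func:`write_timeseries`.

    Unknown columns are preserved as extra channels; an all-empty column
    is kept but reported as absent by :meth:`TimeSeries.has_channel`.
    Parse problems are reported with 1-based data row numbers.
    """
    path = Path(path)
    raw = path.read_text(encoding="utf-8")
    lines = [ln for ln in raw.splitlines() if not ln.startswith("#")]
    if not lines:
        raise TimeSeriesFormatError(f"{path}: empty file")
    try:
        df = pd.read_csv(_io.StringIO("\n".join(lines)), float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise TimeSeriesFormatError(f"{path}: {exc}") from exc
    if TIME_COLUMN not in df.columns:
        raise TimeSeriesFormatError(f"{path}: missing required column {TIME_COLUMN!r}")
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0]) + 1
            raise TimeSeriesFormatError(
                f"{path}: non-numeric value in column {col!r} at data row {row}"
            )
        df[col] = converted
    try:
        return TimeSeries(df, {"source": str(path)})
    except TimeSeriesFormatError as exc:
        raise TimeSeriesFormatError(f"{path}: {exc}") from exc


def _write_kv(path, pairs, header_comment: str | None = None) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        for key, value in pairs:
            if isinstance(value, float):
                fh.write(f"{key} = {_FLOAT_FMT % value}\n")
            else:
                fh.write(f"{key} = {value}\n")


def _read_kv(path) -> dict[str, str]:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"parameter file not found: {path}")
    out: dict[str, str] = {}
    for i, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigError(f"{path}: line {i} is not 'key = value'")
        key, _, value = line.partition("=")
        out[key.strip()] = value.strip()
    return out


def write_lan_parameters(params: LanParameters, path, header_comment: str | None = None) -> None:
    """Write a co-culture parameter set as a flat key-value file."""
    pairs = []
    for attr, letters in _BLOCK_LETTERS.items():
        block: RateBlock = getattr(params, attr)
        values = (
            block.amplitude, block.late_denom, block.early_denom,
            block.half_time, block.exponent,
        )
        pairs.extend(zip(letters, values))
    pairs.extend((name, getattr(params, name)) for name in _SCALARS)
    _write_kv(path, pairs, header_comment)


def read_lan_parameters(path) -> LanParameters:
    """Read a co-culture parameter set written by :func:`write_lan_parameters`."""
    kv = _read_kv(path)
    kwargs = {}
    for attr, letters in _BLOCK_LETTERS.items():
        try:
            amp, late, early, half, expo = (float(kv[k]) for k in letters)
        except KeyError as exc:
            raise ConfigError(f"{path}: missing parameter {exc.args[0]}") from exc
        kwargs[attr] = RateBlock(amp, early, late, half, expo)
    for name in _SCALARS:
        if name not in kv:
            raise ConfigError(f"{path}: missing parameter {name}")
        kwargs[name] = float(kv[name])
    return LanParameters(**kwargs)


def write_calibration(fit_or_calib, path, header_comment: str | None = None) -> None:
    """Write a calibration (optionally with its fit summary) as key-value text."""
    if isinstance(fit_or_calib, CalibrationFit):
        calib = fit_or_calib.calibration
        extra = [("pearson_r", fit_or_calib.pearson_r), ("rss", fit_or_calib.rss),
                 ("n", fit_or_calib.n)]
    else:
        calib, extra = fit_or_calib, []
    pairs = [("slope", calib.slope), ("intercept", calib.intercept),
             ("convention", calib.convention), *extra]
    _write_kv(path, pairs, header_comment)


def read_calibration(path) -> LinearCalibration:
    kv = _read_kv(path)
    for key in ("slope", "intercept", "convention"):
        if key not in kv:
            raise ConfigError(f"{path}: missing calibration field {key}")
    return LinearCalibration(float(kv["slope"]), float(kv["intercept"]), kv["convention"])
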