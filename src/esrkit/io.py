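"""Readers and writers for trace, series, cohort and calibration files.

CSV is the canonical interchange format; XLSX cohorts are supported
read-only through a user-supplied column mapping.  All writers round-trip
through their readers.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import CalibrationParams, PhysicalConstants
from .syllectogram import AggregationIndices, SyllectogramTrace
from .westergren import WestergrenSeries

__all__ = [
    "read_trace", "write_trace", "read_westergren", "write_westergren",
    "read_cohort", "write_cohort", "load_calibration", "save_calibration",
    "write_ai_table", "write_curve",
]

COHORT_COLUMNS = ("sample_id", "donor", "fib_level", "ht", "ai5",
                  "wg_esr_1h", "ve", "alpha", "lambda_s")


class FileFormatError(ValueError):
    """Malformed input file; the message names the offending location."""


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FileFormatError(f"{path}: missing required columns {missing}")


def read_trace(path, sample_id: str | None = None) -> SyllectogramTrace:
    """Read a syllectogram trace CSV with columns ``t_s, ch1[, ch2]``."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["t_s", "ch1"], path)
    t = df["t_s"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise FileFormatError(
            f"{path}: non-monotone t_s at line {bad[0] + 3}")
    channels = [df["ch1"].to_numpy(dtype=float)]
    if "ch2" in df.columns:
        channels.append(df["ch2"].to_numpy(dtype=float))
    dt = float(np.median(np.diff(t))) if t.size > 1 else 0.010
    return SyllectogramTrace(sample_id=sample_id or path.stem,
                             channels=channels, dt=dt)


def write_trace(trace: SyllectogramTrace, path) -> None:
    t = np.arange(trace.n_samples) * trace.dt
    data = {"t_s": t, "ch1": trace.channels[0]}
    if len(trace.channels) == 2:
        data["ch2"] = trace.channels[1]
    pd.DataFrame(data).to_csv(path, index=False)


def read_westergren(path, sample_id: str | None = None,
                    resolution: float = 0.5) -> WestergrenSeries:
    """Read a Westergren series CSV with columns ``t_min, h_mm``."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["t_min", "h_mm"], path)
    t = df["t_min"].to_numpy(dtype=float)
    h = df["h_mm"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise FileFormatError(
            f"{path}: non-monotone t_min at line {bad[0] + 3}")
    neg = np.nonzero(h < 0)[0]
    if neg.size:
        raise FileFormatError(
            f"{path}: negative distance at line {neg[0] + 2}")
    return WestergrenSeries(sample_id=sample_id or path.stem, times=t,
                            distances=h, resolution=resolution)


def write_westergren(series: WestergrenSeries, path) -> None:
    pd.DataFrame({"t_min": series.times, "h_mm": series.distances}).to_csv(
        path, index=False)


def read_cohort(path, mapping: dict | None = None,
                sheet: str | int = 0) -> pd.DataFrame:
    """Read a cohort table from CSV or XLSX.

    ``mapping`` renames source columns to the canonical names
    (``{"source name": "canonical name"}``) — the escape hatch for
    externally deposited spreadsheets with arbitrary headers.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path, sheet_name=sheet)
    else:
        df = pd.read_csv(path)
    if mapping:
        df = df.rename(columns=mapping)
    _require_columns(df, ["ht", "ai5"], path)
    if ((df["ht"] <= 0) | (df["ht"] >= 1)).any():
        raise FileFormatError(f"{path}: ht values must lie in (0, 1)")
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def load_calibration(path) -> tuple:
    """Load ``(CalibrationParams, PhysicalConstants)`` from a JSON file.

    Schema: ``{k, a, b, d, e, f, constants: {rho_e, rho_p, g, r_ef,
    mu_p, n}}``.  The no-aggregation velocity c is always recomputed from
    the constants, never read.
    """
    with open(path) as fh:
        data = json.load(fh)
    params = CalibrationParams.from_dict(data)
    constants = (PhysicalConstants.from_dict(data["constants"])
                 if "constants" in data else PhysicalConstants())
    return params, constants


def save_calibration(params: CalibrationParams,
                     constants: PhysicalConstants, path) -> None:
    data = params.to_dict()
    data["constants"] = constants.to_dict()
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2)
        fh.write("\n")


def write_ai_table(indices: list[AggregationIndices], path) -> None:
    """Write AI results as ``sample_id, window_s, ai, qc_flag`` rows."""
    rows = [
        {"sample_id": ix.sample_id, "window_s": w, "ai": ai,
         "qc_flag": int(ix.qc_flag)}
        for ix in indices for w, ai in sorted(ix.ai.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_curve(curve, path, sidecar: bool = True) -> None:
    """Write a sedimentation curve CSV (+ params sidecar JSON)."""
    path = Path(path)
    pd.DataFrame({"t_min": curve.times, "h_mm": curve.distances}).to_csv(
        path, index=False)
    if sidecar and curve.params:
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump({k: v for k, v in curve.params.items()}, fh, indent=2)
            fh.write("\n")
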