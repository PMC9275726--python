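"""Seeded synthetic cohorts: paired syllectograms and Westergren series.

Emulates the calibration study design — 2 donors x 4 hematocrit levels
(0.25/0.30/0.35/0.40) x 4 fibrinogen levels — with exact ground truth.
Within a donor/fibrinogen cell the four hematocrit samples share one
aggregate size parameter (the same plasma drives aggregation), which makes
the AI-vs-Ht slope exactly k and the calibration fits exactly recoverable
on noiseless cohorts.

Generation inverts the calibration chain so truth is exact at the AI
level: alpha -> Vs = c (1+alpha)^2 -> HAI5 = b + ((Vs - c)/a)^(1/4)
-> AI5 = HAI5 + k (Ht - 0.40), with Ve = Vs (1-Ht)^n and the true 1-h ESR
read off the forward curve.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .constants import (MS_TO_MM_MIN, DEFAULT_CALIBRATION, DEFAULT_CONSTANTS,
                        CalibrationParams, PhysicalConstants)
from .calibration import LAMBDA_FLOOR_MIN
from .physics import AggregationState, build_curve, hindered_factor, stokes_velocity
from .syllectogram import SyllectogramTrace, compute_ai
from .westergren import WestergrenSeries

__all__ = ["NoiseSpec", "SyntheticSpec", "generate_truth",
           "generate_syllectogram", "generate_westergren", "generate_cohort"]

FIB_LEVELS = ("normal", "Fib+", "Fib++", "Fib+++")


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise settings.

    intensity_sd : Gaussian ADC noise on syllectogram samples (a few
        counts of shot/electronic noise on a 12-bit scale).
    reading_quantum : Westergren visual reading resolution [mm]; 0.5 mm
        is the protocol value.
    reading_jitter : uniform visual reading error [mm] before quantization.
    ai_sd : Gaussian repeatability noise on cohort-level AI5 values.
    """

    intensity_sd: float = 8.0
    reading_quantum: float = 0.5
    reading_jitter: float = 0.1
    ai_sd: float = 0.01

    @classmethod
    def noiseless(cls) -> "NoiseSpec":
        return cls(intensity_sd=0.0, reading_quantum=0.0,
                   reading_jitter=0.0, ai_sd=0.0)


@dataclass(frozen=True)
class SyntheticSpec:
    """Design of a synthetic cohort.

    ``n_samples`` rounds up to full donor x fibrinogen x hematocrit cells;
    the default 32 reproduces the 2 x 4 x 4 study design.  ``lambda_mode``
    "regression" draws the time constant from the calibration regression
    (a coherent cohort, exactly recoverable when noiseless); "uniform"
    draws it independently from ``lambda_range_s``.
    """

    n_samples: int = 32
    seed: int = 0
    ht_levels: tuple = (0.25, 0.30, 0.35, 0.40)
    alpha_range: tuple = (0.5, 15.0)
    lambda_range_s: tuple = (5.0, 120.0)
    lambda_mode: str = "regression"
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    params: CalibrationParams = field(default_factory=lambda: DEFAULT_CALIBRATION)
    constants: PhysicalConstants = field(default_factory=lambda: DEFAULT_CONSTANTS)
    trace_duration_s: float = 120.0
    trace_dt_s: float = 0.010

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not (self.alpha_range[0] < self.alpha_range[1]
                and self.lambda_range_s[0] < self.lambda_range_s[1]):
            raise ValueError("parameter ranges must be non-degenerate")
        if self.lambda_mode not in ("regression", "uniform"):
            raise ValueError("lambda_mode must be 'regression' or 'uniform'")


def _true_esr(ht: float, alpha: float, lam_s: float,
              constants: PhysicalConstants) -> float:
    curve = build_curve(ht, AggregationState(alpha, lam_s), constants)
    return curve.at(60.0)


def generate_truth(spec: SyntheticSpec) -> pd.DataFrame:
    """Ground-truth table for a seeded synthetic cohort.

    Columns: sample_id, donor, fib_level, ht, alpha, lambda_s, vs_m_s,
    hai5, ai5, ve, esr_1h_true.  Deterministic given ``spec.seed``; rows
    whose inverse mapping would push AI5 outside [0, 1] are redrawn and
    the redraw count is attached as ``df.attrs["n_redrawn"]``.
    """
    rng = np.random.default_rng(spec.seed)
    p, consts = spec.params, spec.constants
    c = stokes_velocity(consts)
    n_ht = len(spec.ht_levels)
    cells = int(np.ceil(spec.n_samples / n_ht))
    lo, hi = spec.alpha_range
    rows, n_redrawn = [], 0
    sid = 0
    for cell in range(cells):
        donor = f"D{cell % 2 + 1}"
        fib = FIB_LEVELS[(cell // 2) % len(FIB_LEVELS)]
        # fibrinogen level sets the aggregation stratum: quartiles of the
        # alpha range, jittered within the stratum
        q = (cell // 2) % len(FIB_LEVELS)
        for _ in range(200):
            alpha = lo + (hi - lo) * (q + rng.uniform(0.05, 0.95)) / len(FIB_LEVELS)
            vs = c * (1.0 + alpha) ** 2
            hai5 = p.b + ((vs - c) / p.a) ** 0.25
            ai5_all = [hai5 + p.k * (ht - 0.40) for ht in spec.ht_levels]
            if all(0.0 <= ai <= 1.0 for ai in ai5_all):
                break
            n_redrawn += 1
        else:
            raise RuntimeError("could not draw an alpha with AI5 in [0, 1]")
        for ht, ai5 in zip(spec.ht_levels, ai5_all):
            if sid >= spec.n_samples:
                break
            if spec.lambda_mode == "regression":
                # regression-mode lambda is not clipped to lambda_range_s:
                # clipping would pull samples off the regression plane
                lam_min = max(p.d * hai5 + p.e * ht + p.f, LAMBDA_FLOOR_MIN)
                lam_s = lam_min * 60.0
            else:
                lam_s = float(rng.uniform(*spec.lambda_range_s))
            ve = vs * hindered_factor(ht, consts.n) * MS_TO_MM_MIN
            rows.append({
                "sample_id": f"S{sid:03d}", "donor": donor, "fib_level": fib,
                "ht": ht, "alpha": alpha, "lambda_s": lam_s, "vs_m_s": vs,
                "hai5": hai5, "ai5": ai5, "ve": ve,
                "esr_1h_true": _true_esr(ht, alpha, lam_s, consts),
            })
            sid += 1
    df = pd.DataFrame(rows)
    df.attrs["seed"] = spec.seed
    df.attrs["n_redrawn"] = n_redrawn
    return df


# syllectogram shape family: fast rouleaux component (saturating
# exponential) plus a delayed slow aggregation component (squared
# saturating exponential, sigmoidal onset); the slow component lets the
# family reach window-end AI5 below 0.5 while keeping enough dynamic
# range inside the 5-s window for noise robustness
_TAU_FAST_S = 1.0
_TAU_SLOW_S = 6.0
_I_BASE = 400.0
_I_SPAN = 3000.0


def _shape(t: np.ndarray, w: float) -> np.ndarray:
    fast = 1.0 - np.exp(-t / _TAU_FAST_S)
    slow = (1.0 - np.exp(-t / _TAU_SLOW_S)) ** 2
    return _I_BASE + _I_SPAN * (w * fast + (1.0 - w) * slow)


def _noiseless_trace(w: float, spec: SyntheticSpec, sample_id: str) -> SyllectogramTrace:
    t = np.arange(0.0, spec.trace_duration_s + 1e-9, spec.trace_dt_s)
    i = _shape(t, w)
    return SyllectogramTrace(sample_id=sample_id, channels=[i],
                             dt=spec.trace_dt_s, t0_index=[0])


def generate_syllectogram(row, spec: SyntheticSpec,
                          rng: np.random.Generator | None = None) -> SyllectogramTrace:
    """Two-channel synthetic syllectogram whose 5-s AI hits the row's ai5.

    The fast/slow amplitude split is solved numerically so that
    ``compute_ai`` at 5 s returns the target within 1e-3 on the noiseless
    shape; independent Gaussian noise is then added per channel.  The
    trace starts at flow stop, so t0_index is 0 by construction.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    target = float(row["ai5"])

    def gap(w: float) -> float:
        return compute_ai(_noiseless_trace(w, spec, "probe"), 5.0) - target

    g0, g1 = gap(0.0), gap(1.0)
    if not min(g0, g1) <= 0.0 <= max(g0, g1):
        raise ValueError(f"target ai5={target:.3f} outside achievable range "
                         f"[{g0 + target:.3f}, {g1 + target:.3f}] of the "
                         "shape family")
    w = brentq(gap, 0.0, 1.0, xtol=1e-8)
    t = np.arange(0.0, spec.trace_duration_s + 1e-9, spec.trace_dt_s)
    clean = _shape(t, w)
    channels = []
    for _ in range(2):
        noisy = clean + rng.normal(0.0, spec.noise.intensity_sd, clean.size) \
            if spec.noise.intensity_sd > 0 else clean.copy()
        channels.append(np.clip(noisy, 0.0, None))
    return SyllectogramTrace(sample_id=str(row["sample_id"]),
                             channels=channels, dt=spec.trace_dt_s,
                             t0_index=[0, 0])


def _reading_schedule() -> np.ndarray:
    """Westergren reading times [min]: every minute to 30 min, then every
    10 min to 60 min (the protocol thins readings once settling is slow)."""
    return np.concatenate([np.arange(1.0, 31.0), np.arange(40.0, 61.0, 10.0)])


def generate_westergren(row, spec: SyntheticSpec,
                        rng: np.random.Generator | None = None) -> WestergrenSeries:
    """Quantized Westergren series sampled from the row's true curve.

    Adds uniform reading jitter, rounds to the reading quantum and
    enforces monotone non-decreasing readings (a reader never reports the
    interface moving back up).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    t = _reading_schedule()
    curve = build_curve(float(row["ht"]),
                        AggregationState(float(row["alpha"]),
                                         float(row["lambda_s"])),
                        spec.constants)
    h = np.interp(t, curve.times, curve.distances)
    if spec.noise.reading_jitter > 0:
        h = h + rng.uniform(-spec.noise.reading_jitter,
                            spec.noise.reading_jitter, h.size)
    q = spec.noise.reading_quantum
    if q > 0:
        h = np.round(h / q) * q
    h = np.maximum.accumulate(np.clip(h, 0.0, None))
    return WestergrenSeries(sample_id=str(row["sample_id"]), times=t,
                            distances=h, resolution=max(q, 0.0) or 0.0)


def generate_cohort(spec: SyntheticSpec, measure: bool = False):
    """Truth table plus a measured-style cohort table.

    The cohort table carries the columns the calibration fits consume
    (``fib_level, ht, ai5, wg_esr_1h, ve, alpha, lambda_s``).  With
    ``measure=False`` the sedimentation columns are the exact truth and
    only AI repeatability noise (``spec.noise.ai_sd``) is applied; with
    ``measure=True`` they are re-extracted from generated quantized
    Westergren series via :mod:`esrkit.westergren`.

    Returns ``(truth, cohort)``.
    """
    from .westergren import analyze_series  # local import avoids cycle at import time

    truth = generate_truth(spec)
    rng = np.random.default_rng(np.random.default_rng(spec.seed).integers(2**31))
    cohort = truth[["sample_id", "donor", "fib_level", "ht"]].copy()
    ai5 = truth["ai5"].to_numpy().copy()
    if spec.noise.ai_sd > 0:
        ai5 = np.clip(ai5 + rng.normal(0.0, spec.noise.ai_sd, ai5.size), 0.0, 1.0)
    cohort["ai5"] = ai5
    if measure:
        rows = []
        for _, row in truth.iterrows():
            series = generate_westergren(row, spec, rng)
            p = analyze_series(series, float(row["ht"]), spec.constants)
            rows.append((p.wg_esr_1h, p.ve, p.alpha,
                         p.lam.lam_s if not p.lam.excluded else np.nan))
        cohort[["wg_esr_1h", "ve", "alpha", "lambda_s"]] = rows
    else:
        cohort["wg_esr_1h"] = truth["esr_1h_true"]
        cohort["ve"] = truth["ve"]
        cohort["alpha"] = truth["alpha"]
        cohort["lambda_s"] = truth["lambda_s"]
    cohort.attrs["seed"] = spec.seed
    return truth, cohort
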