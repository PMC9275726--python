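"""Calibration fitting and the forward ESR-estimation pipeline.

The estimation chain runs

    (AI5, Ht) -> HAI5 -> Vs -> (Ve, alpha) -> lambda -> sedimentation
    curve -> estimated 1-h ESR,

with the HAI correction factor k, the quartic velocity regression
Vs = a (HAI5 - b)^4 + c (c fixed at the single-cell Stokes velocity) and
the linear time-constant regression lambda = d HAI5 + e Ht + f [min]
fitted from a calibration cohort.  ``ESREstimator`` packages the chain as
a scikit-learn estimator (fit on a cohort table, predict from (ai5, ht)).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import linregress, pearsonr
from sklearn.base import BaseEstimator, RegressorMixin

from .constants import (MS_TO_MM_MIN, DEFAULT_CALIBRATION, DEFAULT_CONSTANTS,
                        CalibrationParams, PhysicalConstants)
from .physics import (AggregationState, SedimentationCurve, build_curve,
                      hindered_factor, stokes_velocity)
from .syllectogram import compute_hai

__all__ = [
    "ESREstimate",
    "ESREstimator",
    "fit_k",
    "predict_vs",
    "predict_lambda",
    "fit_vs_regression",
    "fit_lambda_regression",
    "estimate_esr",
    "evaluate_correlations",
]

#: floor for the predicted aggregation time constant [min] (1 s)
LAMBDA_FLOOR_MIN = 1.0 / 60.0
#: hematocrits whose lambda-vs-HAI5 slopes define the coefficient d
LAMBDA_SLOPE_HTS = (0.25, 0.30)


@dataclass
class ESREstimate:
    """Estimated 1-h ESR with every pipeline intermediate for audit."""

    esr_1h: float          # mm
    curve: SedimentationCurve
    ai5: float
    ht: float
    hai5: float
    vs_m_s: float
    ve_mm_min: float
    alpha: float
    lambda_min: float
    lambda_s: float
    clamped: bool          # HAI5 at/below the regression floor b


def fit_k(cohort: pd.DataFrame, window_s: float = 5) -> tuple:
    """HAI correction factor k: mean over fibrinogen levels of the
    within-level least-squares slope of AI vs Ht.

    Returns ``(k, slopes)`` where ``slopes`` maps fibrinogen level to its
    slope.  Levels with fewer than two distinct Ht values are skipped with
    a warning.
    """
    col = f"ai{int(window_s)}"
    slopes = {}
    for level, grp in cohort.groupby("fib_level"):
        if grp["ht"].nunique() < 2:
            warnings.warn(f"fibrinogen level {level!r} has < 2 Ht values; "
                          "skipped", RuntimeWarning, stacklevel=2)
            continue
        slopes[level] = float(linregress(grp["ht"], grp[col]).slope)
    if not slopes:
        raise ValueError("no fibrinogen level with >= 2 Ht values")
    return float(np.mean(list(slopes.values()))), slopes


def predict_vs(hai5, params: CalibrationParams = DEFAULT_CALIBRATION,
               constants: PhysicalConstants = DEFAULT_CONSTANTS):
    """Aggregate settling velocity Vs [m/s] from the quartic regression.

    Vs = a (HAI5 - b)^4 + c for HAI5 > b; below the physiological floor b
    the quartic (being even) would spuriously rise again, so Vs clamps to
    the no-aggregation Stokes velocity c with a warning.
    """
    hai5 = np.asarray(hai5, dtype=float)
    c = stokes_velocity(constants)
    excess = hai5 - params.b
    if np.any(excess < 0):
        warnings.warn("HAI5 below physiological floor b; Vs clamped to the "
                      "Stokes velocity", RuntimeWarning, stacklevel=2)
    out = params.a * np.clip(excess, 0.0, None) ** 4 + c
    return out if out.ndim else float(out)


def predict_lambda(hai5, ht, params: CalibrationParams = DEFAULT_CALIBRATION):
    """Aggregation time constant [min] from lambda = d HAI5 + e Ht + f,
    floored at 1 s (the regression can go negative for extreme inputs)."""
    hai5 = np.asarray(hai5, dtype=float)
    lam = params.d * hai5 + params.e * np.asarray(ht, dtype=float) + params.f
    if np.any(lam < LAMBDA_FLOOR_MIN):
        warnings.warn("predicted lambda below 1 s; floored", RuntimeWarning,
                      stacklevel=2)
    out = np.clip(lam, LAMBDA_FLOOR_MIN, None)
    return out if out.ndim else float(out)


def _hai5_column(cohort: pd.DataFrame, k: float) -> pd.Series:
    return cohort["ai5"] - k * (cohort["ht"] - 0.40)


def fit_vs_regression(cohort: pd.DataFrame, k: float | None = None,
                      constants: PhysicalConstants = DEFAULT_CONSTANTS) -> tuple:
    """Fit (a, b) of Vs = a (HAI5 - b)^4 + c by nonlinear least squares.

    c stays fixed at the Stokes velocity.  Vs targets [m/s] come from the
    cohort's measured ve [mm/min] and ht via Vs = Ve / (1 - Ht)^n.
    Returns ``(a, b, rms_residual_m_s)``.
    """
    if k is None:
        k = DEFAULT_CALIBRATION.k
    if len(cohort) < 4:
        raise ValueError("need at least 4 samples to fit (a, b)")
    hai5 = _hai5_column(cohort, k).to_numpy()
    if np.ptp(hai5) < 1e-12:
        raise ValueError("degenerate HAI5 spread; (a, b) unidentifiable")
    vs = (cohort["ve"].to_numpy() / MS_TO_MM_MIN
          / hindered_factor(cohort["ht"].to_numpy(), constants.n))
    c = stokes_velocity(constants)

    # fit in Stokes-velocity units (y = Vs/c ~ O(1..1e3)) so the optimizer
    # is well scaled; a_scaled = a/c
    y = vs / c

    def model(h, a_scaled, b):
        return a_scaled * np.clip(h - b, 0.0, None) ** 4 + 1.0

    p0 = (0.05 / c, min(hai5.min() - 1e-3, 0.45))
    popt, _ = curve_fit(model, hai5, y, p0=p0,
                        bounds=([1.0, 0.0], [1e9, 1.0]),
                        x_scale=(p0[0], 0.05),
                        ftol=1e-14, xtol=1e-14, gtol=1e-14, maxfev=50000)
    a = float(popt[0]) * c
    b = float(popt[1])
    rms = float(np.sqrt(np.mean((model(hai5, *popt) - y) ** 2))) * c
    return a, b, rms


def fit_lambda_regression(cohort: pd.DataFrame,
                          k: float | None = None) -> tuple:
    """Fit (d, e, f) of the time-constant regression lambda = d HAI5 + e Ht + f.

    d is the mean of the per-Ht least-squares slopes of lambda [min]
    against HAI5 at Ht 0.25 and 0.30 (where slow settling does not corrupt
    the lambda fits); (e, f) then come from OLS of lambda - d HAI5 on Ht
    over all non-excluded samples.  Rows with missing/excluded lambda are
    dropped.
    """
    if k is None:
        k = DEFAULT_CALIBRATION.k
    data = cohort.dropna(subset=["lambda_s"]).copy()
    if "ve" in data.columns:
        data = data[data["ve"] >= 0.1]
    if data.empty:
        raise ValueError("no samples with a usable lambda")
    data["hai5"] = _hai5_column(data, k)
    data["lam_min"] = data["lambda_s"] / 60.0
    slopes = []
    for ht_lvl in LAMBDA_SLOPE_HTS:
        grp = data[np.isclose(data["ht"], ht_lvl, atol=1e-6)]
        if len(grp) < 2 or grp["hai5"].nunique() < 2:
            raise ValueError(f"missing Ht level {ht_lvl} required for the "
                             "lambda slope")
        slopes.append(float(linregress(grp["hai5"], grp["lam_min"]).slope))
    d = float(np.mean(slopes))
    resid = data["lam_min"] - d * data["hai5"]
    fit = linregress(data["ht"], resid)
    return d, float(fit.slope), float(fit.intercept)


def estimate_esr(ai5: float, ht: float,
                 params: CalibrationParams = DEFAULT_CALIBRATION,
                 constants: PhysicalConstants = DEFAULT_CONSTANTS,
                 t_grid=None) -> ESREstimate:
    """Estimate the 1-h Westergren ESR from a 5-s aggregation index and Ht.

    Runs the full chain HAI5 -> Vs -> (alpha, Ve) -> lambda -> three-phase
    curve and reads the curve at 60 min.  All intermediates are returned.
    """
    hai5 = compute_hai(ai5, ht, k=params.k, window_s=5.0).hai
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        vs = predict_vs(hai5, params, constants)
    c = stokes_velocity(constants)
    alpha = max(float(np.sqrt(vs / c)) - 1.0, 0.0)
    ve_mm = vs * hindered_factor(ht, constants.n) * MS_TO_MM_MIN
    lam_min = predict_lambda(hai5, ht, params)
    state = AggregationState(alpha=alpha, lam=lam_min * 60.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        curve = build_curve(ht, state, constants, t_grid=t_grid)
    esr = curve.at(60.0)
    return ESREstimate(esr_1h=esr, curve=curve, ai5=ai5, ht=ht, hai5=hai5,
                       vs_m_s=vs, ve_mm_min=ve_mm, alpha=alpha,
                       lambda_min=lam_min, lambda_s=lam_min * 60.0,
                       clamped=hai5 <= params.b)


def evaluate_correlations(cohort: pd.DataFrame,
                          windows=(5, 10, 30, 60)) -> pd.DataFrame:
    """Pearson correlations of windowed AIs with the sedimentation parameters.

    Rows: pooled 1-h ESR, then Ve / alpha / lambda stratified by Ht;
    columns: AI windows.  Strata with fewer than 3 samples report NaN.
    """
    cols = [f"ai{w}" for w in windows]
    rows = []

    def corr(sub: pd.DataFrame, target: str) -> list:
        out = []
        for c in cols:
            d = sub[[c, target]].dropna()
            if len(d) < 3 or d[c].nunique() < 2 or d[target].nunique() < 2:
                out.append(np.nan)
            else:
                out.append(pearsonr(d[c], d[target])[0])
        return out

    rows.append(("wg_esr_1h", "pooled", corr(cohort, "wg_esr_1h")))
    for target in ("ve", "alpha", "lambda_s"):
        if target not in cohort.columns:
            continue
        for ht_lvl, grp in cohort.groupby("ht"):
            rows.append((target, f"ht={ht_lvl:.2f}", corr(grp, target)))
    index = pd.MultiIndex.from_tuples([(p, s) for p, s, _ in rows],
                                      names=["parameter", "stratum"])
    return pd.DataFrame([r for _, _, r in rows], index=index, columns=cols)


class ESREstimator(RegressorMixin, BaseEstimator):
    """Scikit-learn estimator for rapid ESR estimation.

    ``fit`` takes a calibration cohort table (columns ``fib_level, ht,
    ai5, ve, lambda_s``) and learns the calibration constants
    (k, a, b, d, e, f); constants not selected in ``refit`` keep their
    init values.  ``predict`` maps rows of (ai5, ht) — a DataFrame with
    those columns or a 2-column array — to estimated 1-h ESR values [mm].

    Parameters default to the reference calibration, so
    ``ESREstimator().fit(None)`` yields a ready-to-use predictor.
    """

    def __init__(self, k: float = 0.284, a: float = 0.0541, b: float = 0.426,
                 d: float = -0.816, e: float = 0.887, f: float = 0.357,
                 refit: tuple = ("k", "a", "b", "d", "e", "f"),
                 constants: PhysicalConstants | None = None):
        self.k = k
        self.a = a
        self.b = b
        self.d = d
        self.e = e
        self.f = f
        self.refit = refit
        self.constants = constants

    def _constants(self) -> PhysicalConstants:
        return self.constants if self.constants is not None else DEFAULT_CONSTANTS

    def fit(self, X=None, y=None):
        """Calibrate from a cohort table; ``X=None`` adopts the init values."""
        values = {p: getattr(self, p) for p in "kabdef"}
        if X is not None:
            cohort = pd.DataFrame(X)
            if "k" in self.refit:
                values["k"], _ = fit_k(cohort)
            if {"a", "b"} & set(self.refit):
                a, b, _ = fit_vs_regression(cohort, k=values["k"],
                                            constants=self._constants())
                if "a" in self.refit:
                    values["a"] = a
                if "b" in self.refit:
                    values["b"] = b
            if {"d", "e", "f"} & set(self.refit):
                d, e, f = fit_lambda_regression(cohort, k=values["k"])
                for name, v in zip("def", (d, e, f)):
                    if name in self.refit:
                        values[name] = v
        for p, v in values.items():
            setattr(self, f"{p}_", v)
        self.c_ = stokes_velocity(self._constants())
        self.calibration_ = CalibrationParams(**values)
        self.n_features_in_ = 2
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "calibration_"):
            raise RuntimeError("ESREstimator is not fitted; call fit() first")

    @staticmethod
    def _as_pairs(X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            return X[["ai5", "ht"]].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n, 2): columns ai5, ht")
        return X

    def predict(self, X) -> np.ndarray:
        """Estimated 1-h ESR [mm] per (ai5, ht) row."""
        self._check_fitted()
        pairs = self._as_pairs(X)
        return np.array([
            estimate_esr(ai5, ht, self.calibration_, self._constants()).esr_1h
            for ai5, ht in pairs])

    def estimate(self, ai5: float, ht: float) -> ESREstimate:
        """Full audited estimate (curve and intermediates) for one sample."""
        self._check_fitted()
        return estimate_esr(ai5, ht, self.calibration_, self._constants())
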