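"""Forward sedimentation model: modified Stokes' law with aggregation kinetics.

The erythrocyte sedimentation curve is modelled in three phases. During the
lag and constant-velocity phases the interface velocity follows Stokes' law
for a growing effective aggregate radius

    Ragg(t) = Ref (1 + alpha (1 - exp(-t/lambda))),

hindered by the Richardson-Zaki factor (1 - Ht)^n.  After the transition
time tau (an empirical power law of the plateau velocity) the packing phase
takes over and the interface relaxes exponentially toward the maximum
settling distance h_inf.

Unit regimes: the Stokes-law kernel works in SI (m, s); the empirical
transition-time, packing and h_inf relations work in clinical units
(mm/min, min, mm).  ``build_curve`` is the boundary where conversion
happens.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .constants import MS_TO_MM_MIN, DEFAULT_CONSTANTS, PhysicalConstants

__all__ = [
    "AggregationState",
    "SedimentationCurve",
    "stokes_velocity",
    "hindered_factor",
    "aggregate_radius",
    "instantaneous_velocity",
    "plateau_velocity",
    "distance_lag_constant",
    "transition_time",
    "h_infinity",
    "packing_distance",
    "curve_distances",
    "build_curve",
    "puccini_eval",
    "fit_puccini",
]

#: below this aggregate size parameter the empirical h_inf relation
#: (which vanishes as alpha -> 0) is considered outside its validity range
ALPHA_FLAG_THRESHOLD = 0.01

#: empirical transition-time power law tau = TAU_COEF * Ve^TAU_EXP
#: (Ve in mm/min, tau in min)
TAU_COEF = 10.317
TAU_EXP = -0.57


@dataclass(frozen=True)
class AggregationState:
    """Aggregation kinetics: saturating aggregate-size parameter and time constant.

    alpha is dimensionless (Ragg saturates at Ref (1 + alpha)); lam is the
    exponential growth time constant in seconds.
    """

    alpha: float
    lam: float

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not self.lam > 0:
            raise ValueError("lam must be > 0")


@dataclass
class SedimentationCurve:
    """A (time, distance) sedimentation curve with its generating parameters.

    times are minutes ascending from 0, distances are mm (non-decreasing).
    ``params`` carries ht, ve_mm_min, alpha, lambda_s, tau_min and h_inf_mm
    (h_inf_mm is None when the packing phase is never reached on the grid).
    ``source`` is one of {"modeled", "measured", "puccini-fit"}.
    """

    times: np.ndarray
    distances: np.ndarray
    params: dict = field(default_factory=dict)
    source: str = "modeled"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        if self.times.shape != self.distances.shape:
            raise ValueError("times and distances must have equal length")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be ascending")
        if np.any(self.distances < 0):
            raise ValueError("distances must be non-negative")

    def at(self, t_min: float) -> float:
        """Linear interpolation of the curve at time ``t_min`` [min]."""
        return float(np.interp(t_min, self.times, self.distances))


def stokes_velocity(constants: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
    """Single-erythrocyte Stokes settling velocity [m/s].

    V = 2 (rho_e - rho_p) g Ref^2 / (9 mu_p); about 9.48e-7 m/s
    (0.057 mm/min) for the default constants — sedimentation without
    aggregation is essentially immeasurable on the Westergren scale.
    """
    c = constants
    return 2.0 * (c.rho_e - c.rho_p) * c.g * c.r_ef**2 / (9.0 * c.mu_p)


def hindered_factor(ht, n: float = DEFAULT_CONSTANTS.n):
    """Richardson-Zaki hindered-settling factor phi = (1 - Ht)^n."""
    ht = np.asarray(ht, dtype=float)
    if np.any((ht < 0) | (ht > 1)):
        raise ValueError("ht must lie in [0, 1]")
    out = (1.0 - ht) ** n
    return out if out.ndim else float(out)


def aggregate_radius(t, state: AggregationState,
                     constants: PhysicalConstants = DEFAULT_CONSTANTS):
    """Effective aggregate radius Ragg(t) [m]; t in seconds."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = constants.r_ef * (1.0 + state.alpha * (1.0 - np.exp(-t / state.lam)))
    return out if out.ndim else float(out)


def instantaneous_velocity(t, ht: float, state: AggregationState,
                           constants: PhysicalConstants = DEFAULT_CONSTANTS):
    """Interface velocity [m/s] at time t [s] during aggregate growth."""
    r = np.asarray(aggregate_radius(t, state, constants))
    phi = hindered_factor(ht, constants.n)
    base = stokes_velocity(constants) * phi / constants.r_ef**2
    out = base * r**2
    return out if out.ndim else float(out)


def plateau_velocity(ht: float, alpha: float,
                     constants: PhysicalConstants = DEFAULT_CONSTANTS,
                     units: str = "m/s") -> float:
    """Constant-phase sedimentation velocity Ve once aggregation has saturated.

    Ve = stokes_velocity * (1 - Ht)^n * (1 + alpha)^2, in ``units``
    ("m/s" or "mm/min").
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    v = stokes_velocity(constants) * hindered_factor(ht, constants.n) * (1.0 + alpha) ** 2
    if units == "mm/min":
        return v * MS_TO_MM_MIN
    if units != "m/s":
        raise ValueError("units must be 'm/s' or 'mm/min'")
    return v


def distance_lag_constant(t, ht: float, state: AggregationState,
                          constants: PhysicalConstants = DEFAULT_CONSTANTS):
    """Settled distance [m] through the lag and constant-velocity phases.

    Analytic time-integral of the instantaneous velocity, with t and
    lambda in seconds:

        pre * [ (1+a)^2 t - 2 a (1+a) L (1 - e^(-t/L)) + (a^2 L / 2)(1 - e^(-2t/L)) ]

    where pre = stokes_velocity * (1 - Ht)^n, a = alpha, L = lambda.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    a, lam = state.alpha, state.lam
    pre = stokes_velocity(constants) * hindered_factor(ht, constants.n)
    em1 = -np.expm1(-t / lam)    # 1 - e^(-t/L)
    em2 = -np.expm1(-2.0 * t / lam)
    out = pre * ((1.0 + a) ** 2 * t
                 - 2.0 * a * (1.0 + a) * lam * em1
                 + 0.5 * a**2 * lam * em2)
    return out if out.ndim else float(out)


def transition_time(ve_mm_min: float) -> float:
    """Transition time tau [min] from constant velocity to packing.

    Empirical power law tau = 10.317 Ve^-0.57 with Ve in mm/min.
    """
    if not ve_mm_min > 0:
        raise ValueError("ve must be > 0")
    return TAU_COEF * ve_mm_min**TAU_EXP


def h_infinity(ht: float, alpha: float) -> float:
    """Maximum settling distance h_inf [mm] = 102 (1 - 0.8 Ht) alpha^0.2.

    Empirical relation; vanishes as alpha -> 0, so it is meaningless for
    non-aggregating blood (a warning is emitted below alpha = 0.01).
    """
    if not 0 < ht < 1:
        raise ValueError("ht must lie in (0, 1)")
    if not alpha > 0:
        raise ValueError("alpha must be > 0 for the packing-distance relation")
    if alpha < ALPHA_FLAG_THRESHOLD:
        warnings.warn(
            "h_infinity is outside its validity range for alpha < 0.01",
            RuntimeWarning, stacklevel=2)
    return 102.0 * (1.0 - 0.8 * ht) * alpha**0.2


def packing_distance(t, tau: float, h_tau: float, v_tau: float, h_inf: float):
    """Settling distance [mm] in the packing phase (t, tau in minutes).

    h(t) = h_inf - (h_inf - h(tau)) exp[ v(tau) / (h_inf - h(tau)) (tau - t) ]

    Continuous at tau with slope v_tau by construction.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < tau - 1e-12):
        raise ValueError("packing phase requires t >= tau")
    if not h_inf > h_tau:
        raise ValueError("packing target below current front (h_inf <= h(tau))")
    if not v_tau > 0:
        raise ValueError("v_tau must be > 0")
    gap = h_inf - h_tau
    out = h_inf - gap * np.exp(v_tau / gap * (tau - t))
    return out if out.ndim else float(out)


def _curve_pieces(ht: float, state: AggregationState,
                  constants: PhysicalConstants):
    """Plateau velocity [mm/min], tau [min], h(tau) [mm], v(tau) [mm/min]."""
    ve_mm = plateau_velocity(ht, state.alpha, constants, units="mm/min")
    tau = transition_time(ve_mm)
    h_tau = distance_lag_constant(tau * 60.0, ht, state, constants) * 1000.0
    v_tau = instantaneous_velocity(tau * 60.0, ht, state, constants) * MS_TO_MM_MIN
    return ve_mm, tau, h_tau, v_tau


def curve_distances(t_min, ht: float, state: AggregationState,
                    constants: PhysicalConstants = DEFAULT_CONSTANTS) -> np.ndarray:
    """Model sedimentation distance [mm] at times ``t_min`` [min].

    Piecewise: analytic lag/constant-phase integral for t <= tau, packing
    relaxation toward h_inf for t > tau.
    """
    t_min = np.atleast_1d(np.asarray(t_min, dtype=float))
    _, tau, h_tau, v_tau = _curve_pieces(ht, state, constants)
    h = np.empty_like(t_min)
    lag = t_min <= tau
    h[lag] = distance_lag_constant(t_min[lag] * 60.0, ht, state, constants) * 1000.0
    if np.any(~lag):
        h_inf = h_infinity(ht, state.alpha)
        h[~lag] = packing_distance(t_min[~lag], tau, h_tau, v_tau, h_inf)
    return h


def build_curve(ht: float, state: AggregationState,
                constants: PhysicalConstants = DEFAULT_CONSTANTS,
                t_grid=None) -> SedimentationCurve:
    """Assemble the three-phase sedimentation curve on a time grid [min].

    Default grid: 0-60 min at 0.5-min steps.  The curve is C0 at the
    transition time tau and slope-continuous because the packing phase is
    anchored at the instantaneous velocity at tau.  If tau exceeds the
    grid end, the curve stays in the lag/constant regime throughout and
    h_inf is not evaluated.
    """
    if t_grid is None:
        t_grid = np.arange(0.0, 60.0 + 1e-9, 0.5)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size == 0 or t_grid[0] != 0.0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly ascending from 0")
    if not 0 < ht < 1:
        raise ValueError("ht must lie in (0, 1)")

    ve_mm, tau, _, _ = _curve_pieces(ht, state, constants)
    h = curve_distances(t_grid, ht, state, constants)
    h_inf = h_infinity(ht, state.alpha) if tau < t_grid[-1] else None
    params = {
        "ht": ht,
        "ve_mm_min": ve_mm,
        "alpha": state.alpha,
        "lambda_s": state.lam,
        "tau_min": tau,
        "h_inf_mm": h_inf,
    }
    return SedimentationCurve(times=t_grid, distances=h, params=params,
                              source="modeled")


def puccini_eval(t, h_inf: float, t50: float, beta: float):
    """Empirical sigmoid h(t) = h_inf [1 - 1/((t/t50)^beta + 1)]; t in min."""
    t = np.asarray(t, dtype=float)
    if not t50 > 0:
        raise ValueError("t50 must be > 0")
    out = h_inf * (1.0 - 1.0 / ((t / t50) ** beta + 1.0))
    return out if out.ndim else float(out)


def fit_puccini(curve: SedimentationCurve):
    """Least-squares fit of the empirical sigmoid to a sedimentation curve.

    Returns ``(h_inf, t50, beta, residual_norm)``.  Requires at least four
    points with at least one beyond half the maximum distance.
    """
    t = curve.times
    h = curve.distances
    if t.size < 4:
        raise ValueError("need at least 4 points to fit the sigmoid")
    hmax = h.max()
    if hmax <= 0:
        raise ValueError("degenerate curve: no sedimentation observed")
    # initial guesses: plateau slightly above observed max, t50 at half-height
    t50_0 = float(np.interp(hmax / 2.0, h, t))
    p0 = (hmax * 1.05, max(t50_0, 1e-3), 2.0)
    try:
        popt, _ = curve_fit(puccini_eval, t, h, p0=p0,
                            bounds=([0, 1e-6, 0.1], [np.inf, np.inf, 20.0]),
                            maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - scipy message passthrough
        raise RuntimeError(f"sigmoid fit did not converge: {exc}") from exc
    resid = float(np.linalg.norm(h - puccini_eval(t, *popt)))
    return float(popt[0]), float(popt[1]), float(popt[2]), resid
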