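"""Physical constants and calibration parameters for the sedimentation model.

The physical constants are literature values for human blood at the
measurement temperature; the calibration parameters tie the optically
measured, hematocrit-corrected aggregation index (HAI) to the parameters
of the sedimentation model and are instrument/cohort specific.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict, replace

#: conversion factor from m/s to the clinical mm/min scale
MS_TO_MM_MIN = 1000.0 * 60.0


@dataclass(frozen=True)
class PhysicalConstants:
    """Literature constants entering Stokes' law and its corrections.

    Attributes
    ----------
    rho_e : float
        Erythrocyte density [kg/m^3].
    rho_p : float
        Plasma density [kg/m^3].
    g : float
        Gravitational acceleration [m/s^2].
    r_ef : float
        Effective (volume-equivalent) erythrocyte radius [m].
    mu_p : float
        Plasma viscosity [Pa s].
    n : float
        Richardson-Zaki hindered-settling exponent; 4.65 is the
        low-Reynolds-number value appropriate for sedimenting blood.
    """

    rho_e: float = 1100.0
    rho_p: float = 1025.0
    g: float = 9.81
    r_ef: float = 3.084e-6
    mu_p: float = 1.64e-3
    n: float = 4.65

    def __post_init__(self) -> None:
        for name in ("rho_e", "rho_p", "g", "r_ef", "mu_p", "n"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.rho_e <= self.rho_p:
            raise ValueError("rho_e must exceed rho_p for settling to occur")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhysicalConstants":
        return cls(**d)

    def replace(self, **kwargs) -> "PhysicalConstants":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class CalibrationParams:
    """Calibration constants linking HAI and hematocrit to sedimentation.

    k   : hematocrit correction factor of the aggregation index
          (AI units per Ht fraction); HAI = AI - k (Ht - 0.40).
    a   : quartic coefficient of the aggregate settling-velocity
          regression Vs = a (HAI5 - b)^4 + c  [m/s per HAI^4].
    b   : minimum physiological HAI5 (regression floor, dimensionless).
    d, e, f : coefficients of the aggregation time-constant regression
          lambda = d HAI5 + e Ht + f, with lambda in minutes.

    The no-aggregation velocity c is never stored: it is the single-cell
    Stokes velocity and is always recomputed from ``PhysicalConstants``.
    """

    k: float = 0.284
    a: float = 0.0541
    b: float = 0.426
    d: float = -0.816
    e: float = 0.887
    f: float = 0.357

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError("a must be positive")
        if not 0.0 < self.b < 1.0:
            raise ValueError("b must lie in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationParams":
        return cls(**{f: d[f] for f in ("k", "a", "b", "d", "e", "f")})

    def replace(self, **kwargs) -> "CalibrationParams":
        return replace(self, **kwargs)


DEFAULT_CONSTANTS = PhysicalConstants()
DEFAULT_CALIBRATION = CalibrationParams()
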