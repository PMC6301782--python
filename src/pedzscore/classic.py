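"""Baseline z-score calculators: WHO first-moments and the Cole/CDC-LMS transform.

The WHO method scores an observation against the reference mean and standard
deviation only, ``z = (x - m) / sd``, and is therefore blind to the skewness of
the reference distribution.  The LMS method parameterizes a skewed reference by
a Box-Cox power L, a median M and a generalized coefficient of variation S,

    z = ((x / M)**L - 1) / (L * S)        for L != 0
    z = log(x / M) / S                    for L == 0

with inverse ``x(z) = M * (1 + L*S*z)**(1/L)`` (``M * exp(S*z)`` at L = 0).
This module also recovers (L, M, S) from a tabulated z-score grid row by least
squares, interpolates LMS parameters between tabulated ages, and classifies
nutritional status from a z-score.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .types import DomainError, MeasurementKind, OutOfRangeError, Sex, ValidationError

#: |L| below which the log branch of the Box-Cox transform is used.
L_LOG_BRANCH_TOL = 1e-7


@dataclass(frozen=True)
class MomentPair:
    """Reference mean and standard deviation, in measurement units."""

    m: float
    sd: float

    def __post_init__(self):
        if not self.sd > 0:
            raise ValidationError(f"sd must be positive, got {self.sd}")


@dataclass(frozen=True)
class LMSTriple:
    """Box-Cox power L, median M and generalized coefficient of variation S."""

    L: float
    M: float
    S: float

    def __post_init__(self):
        if not self.M > 0:
            raise ValidationError(f"M must be positive, got {self.M}")
        if not self.S > 0:
            raise ValidationError(f"S must be positive, got {self.S}")


class StatusCategory(enum.Enum):
    SEVERE_LOW = "severe_low"
    MODERATE_LOW = "moderate_low"
    NORMAL = "normal"
    HIGH = "high"
    VERY_HIGH = "very_high"


#: Clinical terminology for a low score, per measurement kind.
_LOW_TERMS = {
    MeasurementKind.WFA: "underweight",
    MeasurementKind.HFA: "stunting",
    MeasurementKind.BMIFA: "wasting",
}


@dataclass(frozen=True)
class NutritionalStatus:
    """WHO cut-off classification of a z-score (cut-offs at -3, -2, +2, +3)."""

    category: StatusCategory
    kind: MeasurementKind
    z: float

    @property
    def label(self) -> str:
        term = _LOW_TERMS[self.kind]
        return {
            StatusCategory.SEVERE_LOW: f"severe {term}",
            StatusCategory.MODERATE_LOW: f"moderate {term}",
            StatusCategory.NORMAL: "normal",
            StatusCategory.HIGH: "high",
            StatusCategory.VERY_HIGH: "very high",
        }[self.category]


def who_zscore(x, moments: MomentPair):
    """First-moments z-score ``(x - m) / sd``; accepts scalars or arrays."""
    return (np.asarray(x, dtype=float) - moments.m) / moments.sd


def moments_from_grid(z_levels: Sequence[float], values: Sequence[float]) -> MomentPair:
    """Derive (m, sd) from one reference-grid row.

    m is the value at z = 0 and sd the symmetric half-difference of the values
    at z = +1 and z = -1; only first-moment information is retained, so skewness
    in the row is deliberately discarded.
    """
    z = np.asarray(z_levels, dtype=float)
    v = np.asarray(values, dtype=float)
    out = {}
    for level in (-1.0, 0.0, 1.0):
        idx = np.nonzero(np.isclose(z, level, atol=1e-9))[0]
        if idx.size != 1:
            raise ValidationError(f"grid row must contain z = {level:+.0f} exactly once")
        out[level] = float(v[idx[0]])
    return MomentPair(m=out[0.0], sd=(out[1.0] - out[-1.0]) / 2.0)


def lms_zscore(x, p: LMSTriple):
    """Cole's LMS forward transform; continuous in L across 0."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise DomainError("measurement must be positive for the LMS transform")
    if abs(p.L) < L_LOG_BRANCH_TOL:
        return np.log(x / p.M) / p.S
    return ((x / p.M) ** p.L - 1.0) / (p.L * p.S)


def lms_inverse(z, p: LMSTriple):
    """Measurement at z-score ``z``: ``M * (1 + L*S*z)**(1/L)`` (log branch at L=0)."""
    z = np.asarray(z, dtype=float)
    if abs(p.L) < L_LOG_BRANCH_TOL:
        return p.M * np.exp(p.S * z)
    base = 1.0 + p.L * p.S * z
    if np.any(base <= 0):
        raise DomainError(
            f"z outside representable tail: 1 + L*S*z <= 0 for L={p.L}, S={p.S}"
        )
    return p.M * base ** (1.0 / p.L)


def interpolate_lms(table, sex: Sex, age_months: float) -> LMSTriple:
    """Linearly interpolate L, M, S between the two tabulated ages bracketing
    ``age_months`` for ``sex``.  Exact at tabulated ages; no extrapolation."""
    sex = Sex.from_any(sex)
    sub = table.frame[table.frame["sex"] == sex.value]
    if sub.empty:
        raise OutOfRangeError(f"no rows for sex {sex.value}")
    ages = sub["age_months"].to_numpy(dtype=float)
    if not ages[0] <= age_months <= ages[-1]:
        raise OutOfRangeError(
            f"age {age_months} outside reference span [{ages[0]}, {ages[-1]}] for {sex.value}"
        )
    L = float(np.interp(age_months, ages, sub["L"].to_numpy(dtype=float)))
    M = float(np.interp(age_months, ages, sub["M"].to_numpy(dtype=float)))
    S = float(np.interp(age_months, ages, sub["S"].to_numpy(dtype=float)))
    return LMSTriple(L=L, M=M, S=S)


def fit_lms_to_grid(
    z_levels: Sequence[float],
    values: Sequence[float],
    *,
    max_iter: int = 500,
    gtol: float = 1e-10,
) -> tuple[LMSTriple, float]:
    """Recover (L, M, S) from one grid row by least squares.

    Minimizes ``sum_j (x(z_j; L, M, S) - value_j)**2`` starting from L=1,
    M = value(z=0), S from the first-moments row summary.  Returns the fitted
    triple and the final residual norm (callers may flag non-convergence).
    """
    z = np.asarray(z_levels, dtype=float)
    v = np.asarray(values, dtype=float)
    if z.size < 3 or np.unique(z).size != z.size:
        raise ValidationError("need at least 3 distinct z-levels")
    if np.any(np.diff(v) <= 0):
        raise ValidationError("grid row values must be strictly increasing in z")

    mom = moments_from_grid(z, v)
    x0 = np.array([1.0, mom.m, mom.sd / mom.m])

    def residuals(theta):
        L, M, S = theta
        if abs(L) < L_LOG_BRANCH_TOL:
            pred = M * np.exp(S * z)
        else:
            base = 1.0 + L * S * z
            bad = base <= 0
            base = np.where(bad, 1e-12, base)
            pred = M * base ** (1.0 / L)
            pred = np.where(bad, 1e6 * (1.0 + np.abs(z)), pred)
        return pred - v

    sol = least_squares(
        residuals,
        x0,
        bounds=([-10.0, 1e-8, 1e-8], [10.0, np.inf, np.inf]),
        xtol=1e-15,
        ftol=1e-15,
        gtol=gtol,
        max_nfev=max_iter * 4,
    )
    L, M, S = sol.x
    residual = float(math.sqrt(2.0 * sol.cost))
    return LMSTriple(L=float(L), M=float(M), S=float(S)), residual


def classify_status(z: float, kind: MeasurementKind) -> NutritionalStatus:
    """Classify a z-score by the fixed cut-offs -3, -2, +2, +3.

    Intervals are half-open, closed on the lower bound: [-3, -2) is moderate,
    so z = -3 is moderate_low and z = -2 is already normal; likewise z = +2 is
    high and z = +3 very_high.
    """
    kind = MeasurementKind.from_any(kind)
    if not np.isfinite(z):
        raise DomainError(f"z must be finite, got {z}")
    if z < -3:
        cat = StatusCategory.SEVERE_LOW
    elif z < -2:
        cat = StatusCategory.MODERATE_LOW
    elif z < 2:
        cat = StatusCategory.NORMAL
    elif z < 3:
        cat = StatusCategory.HIGH
    else:
        cat = StatusCategory.VERY_HIGH
    return NutritionalStatus(category=cat, kind=kind, z=float(z))


def bmi(weight_kg: float, height_cm: float) -> float:
    """Body-mass index in kg/m^2 from weight in kg and height in cm."""
    if weight_kg <= 0 or height_cm <= 0:
        raise DomainError("weight and height must be positive")
    return weight_kg / (height_cm / 100.0) ** 2
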