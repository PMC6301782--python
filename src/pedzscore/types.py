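"""Shared domain types: sexes, measurement kinds, observations, and error classes."""

from __future__ import annotations

import enum
from dataclasses import dataclass

AGE_MIN_MONTHS = 0.0
AGE_MAX_MONTHS = 240.0

#: z-levels tabulated by the CDC growth-chart z-score files.
DEFAULT_Z_LEVELS = (-2.0, -1.5, -1.0, -0.5, 0.0, 0.5, 1.0, 1.5, 2.0)


class PedzError(Exception):
    """Base class for all package errors."""


class FormatError(PedzError, ValueError):
    """A file does not follow the expected CSV dialect."""


class ValidationError(PedzError, ValueError):
    """Parsed data violates a table invariant (monotonicity, positivity, uniqueness)."""


class DomainError(PedzError, ValueError):
    """A value lies outside the mathematical domain of a transform."""


class OutOfRangeError(PedzError, ValueError):
    """A query age or measurement falls outside the reference's span."""


class CoverageError(PedzError, ValueError):
    """A comparison input does not cover the required (sex, age) cells."""


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"

    @property
    def cdc_code(self) -> int:
        """On-disk CDC convention: 1 = male, 2 = female."""
        return 1 if self is Sex.MALE else 2

    @classmethod
    def from_any(cls, value) -> "Sex":
        """Accept enum, CDC integer code, or a case-insensitive name."""
        if isinstance(value, Sex):
            return value
        if isinstance(value, (int, float)) and not isinstance(value, bool):
            code = int(value)
            if code == 1:
                return cls.MALE
            if code == 2:
                return cls.FEMALE
            raise ValidationError(f"unknown sex code {value!r} (expected 1 or 2)")
        text = str(value).strip().lower()
        if text in {"m", "male", "1"}:
            return cls.MALE
        if text in {"f", "female", "2"}:
            return cls.FEMALE
        raise ValidationError(f"unknown sex value {value!r}")


class MeasurementKind(enum.Enum):
    """Weight-, height- and BMI-for-age references with their fixed units."""

    WFA = ("WFA", "kg")
    HFA = ("HFA", "cm")
    BMIFA = ("BMIFA", "kg_per_m2")

    def __init__(self, code: str, units: str):
        self.code = code
        self.units = units

    @classmethod
    def from_any(cls, value) -> "MeasurementKind":
        if isinstance(value, MeasurementKind):
            return value
        text = str(value).strip().upper()
        for kind in cls:
            if text == kind.code:
                return kind
        raise ValidationError(f"unknown measurement kind {value!r}")


@dataclass(frozen=True)
class Observation:
    """One child record: sex, age in months (0-240), and a positive measurement."""

    sex: Sex
    age_months: float
    value: float
    kind: MeasurementKind

    def __post_init__(self):
        if not AGE_MIN_MONTHS <= self.age_months <= AGE_MAX_MONTHS:
            raise OutOfRangeError(
                f"age {self.age_months} months outside [{AGE_MIN_MONTHS}, {AGE_MAX_MONTHS}]"
            )
        if not self.value > 0:
            raise DomainError(f"measurement must be positive, got {self.value}")
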