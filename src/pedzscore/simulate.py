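"""Seeded cohort simulators for the validation protocol.

Two generators:

* :func:`simulate_cohort` — the height-for-age screening population: three
  age clusters (35, 45 and 65 months by default) with a relative spread of
  10%, heights drawn around the reference median at the drawn age (again 10%
  relative SD) and truncated to 86-121 cm, 3000 records in total.  The
  truncated-normal tails naturally contain implausible observations relative
  to the reference; no separate injection mechanism is used.

* :func:`simulate_stage3_cohort` — a synthetic clinic-style longitudinal
  cohort (212 children, 731 visits by default): each child carries persistent
  height and weight z-scores (correlated), visits advance in age, heights are
  non-decreasing, and BMI is derived from weight and height, never drawn.

Both use one random substream per record (numpy ``SeedSequence`` children), so
growing the cohort never changes earlier records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classic
from .reference import LMSTable
from .types import MeasurementKind, OutOfRangeError, Sex, ValidationError


@dataclass(frozen=True)
class SimulationSpec:
    """Configuration of the three-cluster simulated screening population."""

    group_ages_months: tuple[float, ...] = (35.0, 45.0, 65.0)
    relative_sd: float = 0.10
    height_bounds_cm: tuple[float, float] = (86.0, 121.0)
    n_total: int = 3000
    group_weights: tuple[float, ...] | None = None  # default uniform
    sex_ratio: float = 0.5  # fraction male
    seed: int = 0

    def __post_init__(self):
        if self.n_total < 1:
            raise ValidationError("n_total must be >= 1")
        lo, hi = self.height_bounds_cm
        if not lo < hi:
            raise ValidationError("height bounds must satisfy low < high")
        w = self.weights
        if abs(sum(w) - 1.0) > 1e-12:
            raise ValidationError("group weights must sum to 1")
        if len(w) != len(self.group_ages_months):
            raise ValidationError("one weight per group required")

    @property
    def weights(self) -> tuple[float, ...]:
        if self.group_weights is not None:
            return self.group_weights
        k = len(self.group_ages_months)
        return tuple(1.0 / k for _ in range(k))


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lo: float = -np.inf, hi: float = np.inf) -> float:
    """One truncated-normal draw by rejection; degenerate sd collapses to the
    clipped mean."""
    if sd <= 1e-12:
        return float(min(max(mean, lo), hi))
    for _ in range(10000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise ValidationError(
        f"truncation bounds [{lo}, {hi}] unreachable from N({mean}, {sd}^2)"
    )


def simulate_cohort(spec: SimulationSpec, reference: LMSTable) -> pd.DataFrame:
    """Draw the three-cluster height-for-age population.

    Returns a frame with columns child_id, group, sex, age_months, height_cm,
    weight_kg, bmi (the last two empty for this height-only population).
    """
    if reference.kind is not MeasurementKind.HFA:
        raise ValidationError("simulate_cohort needs a height-for-age reference")
    weights = np.asarray(spec.weights)
    lo, hi = spec.height_bounds_cm
    spans = {sex: reference.age_span(sex) for sex in (Sex.MALE, Sex.FEMALE)}

    records = []
    for i in range(spec.n_total):
        rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 1, i]))
        group = int(rng.choice(len(weights), p=weights))
        mu = spec.group_ages_months[group]
        sex = Sex.MALE if rng.random() < spec.sex_ratio else Sex.FEMALE
        a_lo, a_hi = spans[sex]
        age = _trunc_normal(rng, mu, spec.relative_sd * mu, a_lo, a_hi)
        if not a_lo <= age <= a_hi:
            raise OutOfRangeError(f"reference gap at age {age} for {sex.value}")
        p = classic.interpolate_lms(reference, sex, age)
        height = _trunc_normal(rng, p.M, spec.relative_sd * p.M, lo, hi)
        records.append(
            {
                "child_id": i,
                "group": group,
                "sex": sex.value,
                "age_months": age,
                "height_cm": height,
                "weight_kg": np.nan,
                "bmi": np.nan,
            }
        )
    return pd.DataFrame.from_records(records)


@dataclass(frozen=True)
class Stage3Demographics:
    """Summary-moment targets for the synthetic longitudinal cohort.

    Magnitudes imitate a school-age clinical follow-up population (mean age
    near 116 months with a wide spread, slightly sub-zero height and weight
    z-scores, correlated within child).  Entirely synthetic.
    """

    sex_ratio_male: float = 0.528
    age_mean_months: float = 116.5
    age_sd_months: float = 55.0
    age_range_months: tuple[float, float] = (24.0, 216.0)
    z_height_mean: float = -0.15
    z_height_sd: float = 1.1
    z_weight_mean: float = -0.3
    z_weight_sd: float = 0.9
    height_weight_corr: float = 0.7
    visit_gap_months: tuple[float, float] = (1.0, 6.0)
    #: small per-visit wobble of the weight z-score (children do not track
    #: their weight centile as tightly as their height centile)
    z_weight_visit_sd: float = 0.05


def simulate_stage3_cohort(
    n_children: int = 212,
    visits_total: int = 731,
    demographics: Stage3Demographics | None = None,
    seed: int = 0,
    *,
    references: dict[MeasurementKind, LMSTable],
) -> pd.DataFrame:
    """Synthetic longitudinal cohort with per-child persistent z-scores.

    Returns one row per visit with columns child_id, visit, sex, age_months,
    height_cm, weight_kg, bmi.  Heights are non-decreasing within a child and
    BMI is weight / height^2, derived, never drawn.
    """
    demo = demographics or Stage3Demographics()
    if visits_total < n_children:
        raise ValidationError("visits_total must be >= n_children")
    hfa = references[MeasurementKind.HFA]
    wfa = references[MeasurementKind.WFA]

    # one extra-visit allocation draw, then one substream per child
    alloc_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2, 0]))
    extra = alloc_rng.multinomial(visits_total - n_children, np.full(n_children, 1.0 / n_children))
    corr = demo.height_weight_corr
    if not -1.0 < corr < 1.0:
        raise ValidationError("height_weight_corr must be in (-1, 1)")

    rows = []
    for child in range(n_children):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2, child + 1]))
        n_visits = 1 + int(extra[child])
        sex = Sex.MALE if rng.random() < demo.sex_ratio_male else Sex.FEMALE
        a_lo, a_hi = demo.age_range_months
        age0 = _trunc_normal(rng, demo.age_mean_months, demo.age_sd_months, a_lo, a_hi)
        # correlated persistent z-scores
        e1, e2 = rng.normal(size=2)
        z_h = demo.z_height_mean + demo.z_height_sd * e1
        z_w = demo.z_weight_mean + demo.z_weight_sd * (
            corr * e1 + np.sqrt(1.0 - corr**2) * e2
        )
        age = age0
        last_height = 0.0
        for visit in range(n_visits):
            age = min(age, 240.0)
            ph = classic.interpolate_lms(hfa, sex, age)
            pw = classic.interpolate_lms(wfa, sex, age)
            height = float(classic.lms_inverse(z_h, ph))
            height = max(height, last_height)  # growth constraint guard
            last_height = height
            zw_visit = z_w + demo.z_weight_visit_sd * rng.normal()
            weight = float(classic.lms_inverse(zw_visit, pw))
            rows.append(
                {
                    "child_id": child,
                    "visit": visit,
                    "sex": sex.value,
                    "age_months": age,
                    "height_cm": height,
                    "weight_kg": weight,
                    "bmi": classic.bmi(weight, height),
                }
            )
            gap = rng.uniform(*demo.visit_gap_months)
            age = min(age + gap, 240.0)
    frame = pd.DataFrame.from_records(rows)
    assert len(frame) == visits_total
    return frame


def cohort_observations(frame: pd.DataFrame, kind: MeasurementKind) -> pd.DataFrame:
    """Long-form (sex, age_months, value) view of a cohort frame for ``kind``."""
    col = {
        MeasurementKind.HFA: "height_cm",
        MeasurementKind.WFA: "weight_kg",
        MeasurementKind.BMIFA: "bmi",
    }[MeasurementKind.from_any(kind)]
    out = frame[["sex", "age_months", col]].rename(columns={col: "value"})
    return out.dropna(subset=["value"]).reset_index(drop=True)
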