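"""Three-stage comparison of the z-score calculators.

Stage 1 scores every (sex, age, z, value) cell of a reference grid with all
three methods and summarizes the residuals ``true z - calculated z``.
Stage 2 compares the CDC-LMS and GP calculators on a simulated height-for-age
population via the relative ("absolute") error |z_gp - z_lms| / |z_lms|,
banded at 10% and 30%.  Stage 3 runs paired-difference analysis on a
multi-measurement cohort: per-kind Wilcoxon signed-rank tests, a one-way ANOVA
across the kinds' difference distributions, and per-observation >5%-error
flags for growth-chart overlays.

Relative error divides by the CDC-LMS z-score, which is ill-defined near
z = 0 — exactly where the methods disagree most.  Pairs with |z_lms| below a
guard threshold (default 0.01) are excluded from the band fractions and
reported separately instead of silently dividing by a near-zero number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.stats

from . import classic
from .gp import GPZScoreResults
from .reference import LMSTable, ReferenceGrid
from .types import CoverageError, MeasurementKind, Sex, ValidationError

METHODS = ("WHO", "CDC_LMS", "GPR")

#: |z_lms| below this is treated as a near-zero denominator (guarded pair).
DEFAULT_GUARD = 0.01


@dataclass(frozen=True)
class ErrorBandSummary:
    """Stage-2 relative-error band fractions."""

    n_pairs: int
    fraction_gt_30pct: float
    fraction_10_to_30pct: float
    flagged_near_zero: int

    def as_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "fraction_gt_30pct": self.fraction_gt_30pct,
            "fraction_10_to_30pct": self.fraction_10_to_30pct,
            "flagged_near_zero": self.flagged_near_zero,
        }


@dataclass
class ComparisonReport:
    """Aggregates for one comparison stage; every number is recomputable from
    the accompanying per-record frame."""

    stage: int
    summaries: dict = field(default_factory=dict)
    band_summary: ErrorBandSummary | None = None
    tests: dict = field(default_factory=dict)
    records: pd.DataFrame | None = None

    def as_dict(self) -> dict:
        out = {"stage": self.stage, "summaries": self.summaries, "tests": self.tests}
        if self.band_summary is not None:
            out["band_summary"] = self.band_summary.as_dict()
        return out


def _summary(x: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return {
        "n": int(x.size),
        "min": float(np.min(x)),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(np.max(x)),
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
    }


def relative_error(z_ref: float, z_alt: float,
                   guard: float = DEFAULT_GUARD) -> tuple[float, bool]:
    """Relative error |z_alt - z_ref| / |z_ref| with a near-zero guard.

    When |z_ref| < guard the absolute difference is returned instead and the
    guarded flag is set; such pairs belong in the near-zero tally, not the
    band fractions.
    """
    if not (np.isfinite(z_ref) and np.isfinite(z_alt)):
        raise ValidationError("relative_error requires finite inputs")
    if abs(z_ref) < guard:
        return abs(z_alt - z_ref), True
    return abs(z_alt - z_ref) / abs(z_ref), False


def _check_coverage(grid_or_ages, lms: LMSTable):
    if isinstance(grid_or_ages, ReferenceGrid):
        frame = grid_or_ages.frame[["sex", "age_months"]]
    else:
        frame = grid_or_ages
    missing = []
    for sex_val, sub in frame.groupby("sex"):
        lo, hi = lms.age_span(Sex(sex_val))
        ages = sub["age_months"].to_numpy(dtype=float)
        bad = ages[(ages < lo) | (ages > hi)]
        missing.extend((sex_val, float(a)) for a in np.unique(bad))
    if missing:
        raise CoverageError(f"reference does not cover cells: {missing[:10]}")


# ---------------------------------------------------------------------------
# stage 1


def stage1_residuals(grid: ReferenceGrid, lms: LMSTable,
                     gpr: GPZScoreResults) -> tuple[pd.DataFrame, ComparisonReport]:
    """Score every grid cell with WHO, CDC-LMS and GP calculators.

    Returns the per-cell residual records (one row per cell x method) and a
    report with per-method residual summaries plus residual-vs-age and
    calculated-vs-true series.
    """
    if gpr.kind is not grid.kind:
        raise ValidationError("GP model kind does not match the grid")
    _check_coverage(grid, lms)
    z_levels = np.asarray(grid.z_levels)
    vals = grid.values

    rows = []
    sexes, ages, xs, zs = [], [], [], []
    for i, (_, row) in enumerate(grid.frame.iterrows()):
        sex, age = row["sex"], float(row["age_months"])
        mom = classic.moments_from_grid(z_levels, vals[i])
        p = classic.interpolate_lms(lms, Sex(sex), age)
        z_who = classic.who_zscore(vals[i], mom)
        z_lms = classic.lms_zscore(vals[i], p)
        for j, z in enumerate(z_levels):
            x = vals[i, j]
            sexes.append(sex)
            ages.append(age)
            xs.append(x)
            zs.append(float(z))
            rows.append((sex, age, float(z), x, "WHO", float(z_who[j])))
            rows.append((sex, age, float(z), x, "CDC_LMS", float(z_lms[j])))

    mean, _ = gpr.predict(sexes, ages, xs)
    for k, z_hat in enumerate(mean):
        sex, age, z, x = sexes[k], ages[k], zs[k], xs[k]
        rows.append((sex, age, z, x, "GPR", float(z_hat)))

    records = pd.DataFrame(
        rows, columns=["sex", "age_months", "true_z", "value", "method", "calculated_z"]
    )
    records["kind"] = grid.kind.code
    records["residual"] = records["true_z"] - records["calculated_z"]

    report = ComparisonReport(stage=1, records=records)
    for method in METHODS:
        sub = records[records["method"] == method]
        report.summaries[method] = _summary(sub["residual"].to_numpy())
    return records, report


# ---------------------------------------------------------------------------
# stage 2


def stage2_compare(cohort: pd.DataFrame, lms: LMSTable, gpr: GPZScoreResults,
                   guard: float = DEFAULT_GUARD) -> tuple[ErrorBandSummary, pd.DataFrame]:
    """CDC-LMS vs GP relative-error analysis on a simulated HFA population.

    ``cohort`` is a long-form frame with columns sex, age_months, value
    (heights in cm).  Returns the band summary and the per-observation pair
    frame (z_lms, z_gpr, relative error, guard flag, |z| locality bands).
    """
    _check_coverage(cohort[["sex", "age_months"]], lms)
    z_lms = np.array(
        [
            float(
                classic.lms_zscore(
                    v, classic.interpolate_lms(lms, Sex(s), a)
                )
            )
            for s, a, v in zip(cohort["sex"], cohort["age_months"], cohort["value"])
        ]
    )
    z_gpr, _ = gpr.predict(
        list(cohort["sex"]),
        cohort["age_months"].to_numpy(dtype=float),
        cohort["value"].to_numpy(dtype=float),
    )
    pairs = cohort.copy()
    pairs["z_lms"] = z_lms
    pairs["z_gpr"] = z_gpr
    err_flag = [relative_error(a, b, guard) for a, b in zip(z_lms, z_gpr)]
    pairs["rel_error"] = [e for e, _ in err_flag]
    pairs["guarded"] = [f for _, f in err_flag]
    pairs["abs_z_band"] = pd.cut(
        np.abs(z_lms), bins=[0.0, 1.0, 2.0, np.inf],
        labels=["|z|<=1", "1<|z|<=2", "|z|>2"], include_lowest=True,
    )

    ok = ~pairs["guarded"].to_numpy(dtype=bool)
    err = pairs.loc[ok, "rel_error"].to_numpy()
    n = int(ok.sum())
    summary = ErrorBandSummary(
        n_pairs=n,
        fraction_gt_30pct=float(np.mean(err > 0.30)) if n else 0.0,
        fraction_10_to_30pct=float(np.mean((err > 0.10) & (err <= 0.30))) if n else 0.0,
        flagged_near_zero=int((~ok).sum()),
    )
    return summary, pairs


# ---------------------------------------------------------------------------
# stage 3


def wilcoxon_signed_rank(differences) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (Wilcoxon's original convention).  Exact null
    distribution for n <= 25; normal approximation with continuity correction
    above.  All-zero differences are degenerate: statistic 0, p = 1.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0.0]
    if d.size == 0:
        return 0.0, 1.0
    if d.size <= 25:
        res = scipy.stats.wilcoxon(d, zero_method="wilcox", method="exact")
    else:
        res = scipy.stats.wilcoxon(
            d, zero_method="wilcox", method="approx", correction=True
        )
    return float(res.statistic), float(res.pvalue)


def one_way_anova(*groups) -> tuple[float, float]:
    """One-way ANOVA across groups; identical groups give F = 0, p = 1."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValidationError("need >= 2 groups with >= 2 values each")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0.0:
        return 0.0, 1.0
    f, p = scipy.stats.f_oneway(*arrays)
    return float(f), float(p)


def stage3_compare(
    cohort: pd.DataFrame,
    lms_tables: Mapping[MeasurementKind, LMSTable],
    gpr_models: Mapping[MeasurementKind, GPZScoreResults],
    guard: float = DEFAULT_GUARD,
    flag_threshold: float = 0.05,
) -> ComparisonReport:
    """Paired CDC-LMS vs GP analysis on a multi-measurement cohort.

    ``cohort`` carries one row per visit with height_cm / weight_kg / bmi
    columns.  Per kind: paired differences ``z_lms - z_gpr`` with summary and
    95% CI of the mean, a Wilcoxon signed-rank p; across kinds a one-way
    ANOVA on the difference distributions.  Each observation gets a >5%
    relative-error flag ("error" / "ok" / "near_zero" when the denominator
    guard fires) for chart overlays.
    """
    from .simulate import cohort_observations

    records = []
    diffs_by_kind = {}
    for kind in (MeasurementKind.WFA, MeasurementKind.HFA, MeasurementKind.BMIFA):
        if kind not in lms_tables or kind not in gpr_models:
            continue
        obs = cohort_observations(cohort, kind)
        if obs.empty:
            continue
        lms = lms_tables[kind]
        _check_coverage(obs[["sex", "age_months"]], lms)
        z_lms = np.array(
            [
                float(classic.lms_zscore(v, classic.interpolate_lms(lms, Sex(s), a)))
                for s, a, v in zip(obs["sex"], obs["age_months"], obs["value"])
            ]
        )
        z_gpr, _ = gpr_models[kind].predict(
            list(obs["sex"]),
            obs["age_months"].to_numpy(dtype=float),
            obs["value"].to_numpy(dtype=float),
        )
        err_flag = [relative_error(a, b, guard) for a, b in zip(z_lms, z_gpr)]
        frame = obs.copy()
        frame["kind"] = kind.code
        frame["z_lms"] = z_lms
        frame["z_gpr"] = z_gpr
        frame["difference"] = z_lms - z_gpr
        frame["rel_error"] = [e for e, _ in err_flag]
        frame["flag"] = [
            "near_zero" if guarded else ("error" if e > flag_threshold else "ok")
            for e, guarded in err_flag
        ]
        records.append(frame)
        diffs_by_kind[kind.code] = frame["difference"].to_numpy()

    if not records:
        raise ValidationError("cohort contains no scorable observations")
    all_records = pd.concat(records, ignore_index=True)

    report = ComparisonReport(stage=3, records=all_records)
    for code, d in diffs_by_kind.items():
        s = _summary(d)
        if d.size > 1:
            half = 1.96 * s["sd"] / np.sqrt(d.size)
            s["ci95_mean"] = [s["mean"] - half, s["mean"] + half]
        if d.size >= 2:
            stat, p = wilcoxon_signed_rank(d)
            report.tests[f"wilcoxon_p_{code}"] = p
            report.tests[f"wilcoxon_stat_{code}"] = stat
        else:
            report.tests[f"wilcoxon_p_{code}"] = None
        sub = all_records[all_records["kind"] == code]
        s["n_flagged_error"] = int((sub["flag"] == "error").sum())
        s["n_flagged_near_zero"] = int((sub["flag"] == "near_zero").sum())
        report.summaries[code] = s
    if len(diffs_by_kind) >= 2 and all(d.size >= 2 for d in diffs_by_kind.values()):
        f, p = one_way_anova(*diffs_by_kind.values())
        report.tests["anova_F"] = f
        report.tests["anova_p"] = p
    return report
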