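"""Reference-table containers and I/O in the CDC growth-chart CSV dialect.

Two table shapes circulate in pediatric anthropometry:

* a *z-score grid* — measurement values tabulated at fixed z-levels
  (-2, -1.5, ..., +2) per sex and age in months; and
* an *LMS parameter table* — Box-Cox power L, median M and coefficient of
  variation S per sex and age, from which any z-score or centile follows in
  closed form.

Both are stored as comma-separated UTF-8 CSV with a header, sex coded 1 = male
and 2 = female and age in an ``Agemos`` column, so genuine CDC files load
unmodified.  A seeded synthetic-table generator built on smooth age trends
through the LMS closed form makes every downstream computation testable
without any download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import classic
from .types import (
    DEFAULT_Z_LEVELS,
    FormatError,
    MeasurementKind,
    Sex,
    ValidationError,
)

_SEX_ALIASES = {"sex", "gender"}
_AGE_ALIASES = {"agemos", "age", "age_months"}


# ---------------------------------------------------------------------------
# containers


@dataclass
class LMSTable:
    """Per-(sex, age) Box-Cox parameters, sorted by sex then age."""

    kind: MeasurementKind
    frame: pd.DataFrame  # columns: sex (str), age_months, L, M, S

    def __post_init__(self):
        f = self.frame.reset_index(drop=True)
        f = f.sort_values(["sex", "age_months"], kind="stable").reset_index(drop=True)
        if f.duplicated(subset=["sex", "age_months"]).any():
            dup = f[f.duplicated(subset=["sex", "age_months"])].iloc[0]
            raise ValidationError(
                f"duplicate (sex, age) row: ({dup['sex']}, {dup['age_months']})"
            )
        for col, name in (("M", "M"), ("S", "S")):
            bad = f.index[f[col] <= 0]
            if len(bad):
                raise ValidationError(f"{name} <= 0 in row {int(bad[0])}")
        self.frame = f

    @property
    def sexes(self) -> list[Sex]:
        return [Sex(s) for s in self.frame["sex"].unique()]

    def age_span(self, sex: Sex) -> tuple[float, float]:
        ages = self.frame.loc[self.frame["sex"] == sex.value, "age_months"]
        return float(ages.min()), float(ages.max())

    def lookup(self, sex: Sex, age_months: float) -> classic.LMSTriple:
        """Interpolated (L, M, S) at an arbitrary age; exact at tabulated ages."""
        return classic.interpolate_lms(self, sex, age_months)


@dataclass
class ReferenceGrid:
    """Measurement values indexed by (sex, age, z-level) for one measurement kind."""

    kind: MeasurementKind
    z_levels: tuple[float, ...]
    frame: pd.DataFrame = field(repr=False)  # sex, age_months, v0..v{k-1}

    def __post_init__(self):
        z = np.asarray(self.z_levels, dtype=float)
        if np.any(np.diff(z) <= 0):
            raise ValidationError("z_levels must be strictly increasing")
        self.z_levels = tuple(float(v) for v in z)
        f = self.frame.reset_index(drop=True)
        f = f.sort_values(["sex", "age_months"], kind="stable").reset_index(drop=True)
        if f.duplicated(subset=["sex", "age_months"]).any():
            dup = f[f.duplicated(subset=["sex", "age_months"])].iloc[0]
            raise ValidationError(
                f"duplicate (sex, age) row: ({dup['sex']}, {dup['age_months']})"
            )
        vals = f[self.value_columns].to_numpy(dtype=float)
        bad = np.nonzero(~np.all(np.diff(vals, axis=1) > 0, axis=1))[0]
        if bad.size:
            i = int(bad[0])
            raise ValidationError(
                f"row {i} (sex={f.loc[i, 'sex']}, age={f.loc[i, 'age_months']}): "
                "values not strictly increasing across z-levels"
            )
        self.frame = f

    @property
    def value_columns(self) -> list[str]:
        return [f"v{i}" for i in range(len(self.z_levels))]

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    @property
    def n_points(self) -> int:
        """Flattened (sex, age, z) point count — the GP training-set size."""
        return self.n_rows * len(self.z_levels)

    @property
    def values(self) -> np.ndarray:
        """(n_rows, n_z) array of measurement values."""
        return self.frame[self.value_columns].to_numpy(dtype=float)

    def flatten(self) -> pd.DataFrame:
        """Long form: one row per (sex, age, z, value) training point."""
        rows = []
        vals = self.values
        for i, (_, row) in enumerate(self.frame.iterrows()):
            for j, z in enumerate(self.z_levels):
                rows.append((row["sex"], float(row["age_months"]), z, vals[i, j]))
        return pd.DataFrame(rows, columns=["sex", "age_months", "z", "value"])


# ---------------------------------------------------------------------------
# readers / writers


def _canon_columns(columns: Sequence[str]) -> dict[str, str]:
    """Map raw header names to canonical roles; raise if the header is absent."""
    mapping = {}
    for col in columns:
        key = str(col).strip().lower()
        if key in _SEX_ALIASES:
            mapping[col] = "sex"
        elif key in _AGE_ALIASES:
            mapping[col] = "age_months"
    return mapping


def _check_header(path) -> pd.DataFrame:
    try:
        raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file, expected a CSV header") from None
    # a header whose every field parses as a number is data, not a header
    numericish = all(_is_number(c) for c in raw.columns)
    if numericish:
        raise FormatError(f"{path}: missing header row")
    return raw


def _is_number(text: str) -> bool:
    try:
        float(str(text))
        return True
    except ValueError:
        return False


def read_zscore_table(path, kind: MeasurementKind) -> ReferenceGrid:
    """Read a CDC-dialect z-score table (sex, Agemos, one column per z-level)."""
    kind = MeasurementKind.from_any(kind)
    raw = _check_header(path)
    mapping = _canon_columns(raw.columns)
    roles = set(mapping.values())
    if "sex" not in roles or "age_months" not in roles:
        raise FormatError(f"{path}: need sex and age columns, got {list(raw.columns)}")
    z_cols = [c for c in raw.columns if c not in mapping]
    if not z_cols:
        raise FormatError(f"{path}: no z-level columns found")
    try:
        z_levels = [float(c) for c in z_cols]
    except ValueError:
        raise FormatError(
            f"{path}: z-level columns must be numeric labels, got {z_cols}"
        ) from None
    order = np.argsort(z_levels)
    z_cols = [z_cols[i] for i in order]
    z_levels = sorted(z_levels)

    df = raw.rename(columns=mapping)
    records = []
    for i, row in df.iterrows():
        cells = [row[c] for c in z_cols] + [row["age_months"]]
        if any(not _is_number(c) for c in cells):
            raise ValidationError(f"{path}: non-numeric cell in data row {i}")
        sex = Sex.from_any(row["sex"])
        records.append(
            [sex.value, float(row["age_months"])] + [float(row[c]) for c in z_cols]
        )
    frame = pd.DataFrame(
        records, columns=["sex", "age_months"] + [f"v{i}" for i in range(len(z_cols))]
    )
    return ReferenceGrid(kind=kind, z_levels=tuple(z_levels), frame=frame)


def read_lms_table(path, kind: MeasurementKind) -> LMSTable:
    """Read a CDC-dialect LMS parameter table (sex, Agemos, L, M, S)."""
    kind = MeasurementKind.from_any(kind)
    raw = _check_header(path)
    mapping = _canon_columns(raw.columns)
    for col in raw.columns:
        if str(col).strip().upper() in {"L", "M", "S"}:
            mapping[col] = str(col).strip().upper()
    df = raw.rename(columns=mapping)
    needed = {"sex", "age_months", "L", "M", "S"}
    if not needed <= set(df.columns):
        raise FormatError(
            f"{path}: need columns sex, age, L, M, S; got {list(raw.columns)}"
        )
    records = []
    for i, row in df.iterrows():
        cells = [row[c] for c in ("age_months", "L", "M", "S")]
        if any(not _is_number(c) for c in cells):
            raise ValidationError(f"{path}: non-numeric cell in data row {i}")
        sex = Sex.from_any(row["sex"])
        L, M, S = (float(row[c]) for c in ("L", "M", "S"))
        if M <= 0 or S <= 0:
            raise ValidationError(f"{path}: M/S must be positive in data row {i}")
        records.append([sex.value, float(row["age_months"]), L, M, S])
    frame = pd.DataFrame(records, columns=["sex", "age_months", "L", "M", "S"])
    return LMSTable(kind=kind, frame=frame)


def write_zscore_table(grid: ReferenceGrid, path) -> None:
    """Write a grid in the CDC dialect (sex 1/2, Agemos, z-level columns)."""
    out = pd.DataFrame()
    out["Sex"] = [Sex(s).cdc_code for s in grid.frame["sex"]]
    out["Agemos"] = grid.frame["age_months"].to_numpy()
    for j, z in enumerate(grid.z_levels):
        out[f"{z:g}"] = grid.frame[f"v{j}"].to_numpy()
    out.to_csv(path, index=False)


def write_lms_table(table: LMSTable, path) -> None:
    out = pd.DataFrame()
    out["Sex"] = [Sex(s).cdc_code for s in table.frame["sex"]]
    out["Agemos"] = table.frame["age_months"].to_numpy()
    for col in ("L", "M", "S"):
        out[col] = table.frame[col].to_numpy()
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# synthetic reference generation


@dataclass(frozen=True)
class TrendSpec:
    """Smooth per-sex age trends for L, M, S.

    Each entry maps a sex to a callable ``age_months -> value``.  The defaults
    below imitate the broad magnitudes of published growth references — a
    saturating median for height, a convex one for weight, the characteristic
    BMI dip in mid-childhood — without claiming any real chart's values.
    """

    L: dict[Sex, Callable[[np.ndarray], np.ndarray]]
    M: dict[Sex, Callable[[np.ndarray], np.ndarray]]
    S: dict[Sex, Callable[[np.ndarray], np.ndarray]]


def _scaled(fn, factor):
    return lambda a: factor * fn(a)


def default_trend(kind: MeasurementKind) -> TrendSpec:
    """Built-in trend resembling growth-chart magnitudes for ``kind``."""
    kind = MeasurementKind.from_any(kind)
    a = np.asarray
    if kind is MeasurementKind.HFA:
        M_male = lambda t: 50.0 + 130.0 * a(t, dtype=float) / (a(t, dtype=float) + 70.0)
        return TrendSpec(
            L={s: (lambda t: np.full_like(a(t, dtype=float), 1.0)) for s in Sex},
            M={Sex.MALE: M_male, Sex.FEMALE: _scaled(M_male, 0.985)},
            S={s: (lambda t: 0.035 + 0.010 * a(t, dtype=float) / 240.0) for s in Sex},
        )
    if kind is MeasurementKind.WFA:
        M_male = lambda t: (
            3.4
            + 16.0 * a(t, dtype=float) / (a(t, dtype=float) + 40.0)
            + 0.18 * a(t, dtype=float)
        )
        return TrendSpec(
            L={s: (lambda t: -0.3 - 0.9 * a(t, dtype=float) / 240.0) for s in Sex},
            M={Sex.MALE: M_male, Sex.FEMALE: _scaled(M_male, 0.96)},
            S={s: (lambda t: 0.11 + 0.08 * a(t, dtype=float) / 240.0) for s in Sex},
        )
    # BMIFA: median dips around age 5 then rises through adolescence
    M_male = lambda t: 15.4 + 6.1 * ((a(t, dtype=float) - 60.0) / 180.0) ** 2
    return TrendSpec(
        L={s: (lambda t: -1.8 + 0.6 * a(t, dtype=float) / 240.0) for s in Sex},
        M={Sex.MALE: M_male, Sex.FEMALE: _scaled(M_male, 0.99)},
        S={s: (lambda t: 0.08 + 0.05 * a(t, dtype=float) / 240.0) for s in Sex},
    )


def synth_lms_table(
    kind: MeasurementKind,
    age_grid: Sequence[float],
    trend: TrendSpec | None = None,
    seed: int = 0,
    jitter: float = 0.01,
) -> LMSTable:
    """Generate a synthetic LMS table from smooth age trends.

    A seeded, age-linear log-scale perturbation (relative scale ``jitter``) is
    applied per sex to M and S so distinct seeds give distinct but equally
    smooth references; L follows its trend exactly (keeping, e.g., a
    symmetric L = 1 height reference exactly symmetric for every seed).
    ``jitter=0`` reproduces the trend exactly.  The output always satisfies
    the LMSTable invariants; a trend driving M or S non-positive raises.
    """
    kind = MeasurementKind.from_any(kind)
    trend = trend or default_trend(kind)
    ages = np.asarray(sorted(age_grid), dtype=float)
    if ages.size == 0:
        raise ValidationError("age_grid must be non-empty")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC0FFEE]))
    records = []
    for sex in (Sex.MALE, Sex.FEMALE):
        t = ages / 240.0
        pert = {}
        for name in ("M", "S"):
            e0, e1 = rng.normal(0.0, jitter, size=2)
            pert[name] = np.exp(e0 + e1 * t) if jitter > 0 else np.ones_like(t)
        L = trend.L[sex](ages)
        M = trend.M[sex](ages) * pert["M"]
        S = trend.S[sex](ages) * pert["S"]
        if np.any(M <= 0) or np.any(S <= 0):
            raise ValidationError(f"trend produced non-positive M or S for {sex.value}")
        if np.any(np.abs(L) > 10):
            raise ValidationError(f"trend produced |L| > 10 for {sex.value}")
        for age, l, m, s in zip(ages, L, M, S):
            records.append([sex.value, float(age), float(l), float(m), float(s)])
    frame = pd.DataFrame(records, columns=["sex", "age_months", "L", "M", "S"])
    return LMSTable(kind=kind, frame=frame)


def grid_from_lms(
    table: LMSTable, z_levels: Sequence[float] = DEFAULT_Z_LEVELS
) -> ReferenceGrid:
    """Evaluate the LMS inverse ``x(z) = M (1 + L S z)^{1/L}`` on a z-level grid."""
    z = np.asarray(z_levels, dtype=float)
    records = []
    for _, row in table.frame.iterrows():
        p = classic.LMSTriple(L=row["L"], M=row["M"], S=row["S"])
        base_ok = (abs(p.L) < classic.L_LOG_BRANCH_TOL) or np.all(
            1.0 + p.L * p.S * z > 0
        )
        if not base_ok:
            bad = z[1.0 + p.L * p.S * z <= 0]
            raise ValidationError(
                f"1 + L*S*z <= 0 at sex={row['sex']}, age={row['age_months']}, "
                f"z={bad.tolist()}"
            )
        values = classic.lms_inverse(z, p)
        records.append([row["sex"], float(row["age_months"])] + list(map(float, values)))
    frame = pd.DataFrame(
        records, columns=["sex", "age_months"] + [f"v{i}" for i in range(z.size)]
    )
    return ReferenceGrid(kind=table.kind, z_levels=tuple(z.tolist()), frame=frame)
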