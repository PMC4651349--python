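"""Pediatric growth references: BMI, blood-pressure and neck-circumference
percentiles and the binary anthropometric flags used by the score.

Three pluggable reference tables drive the computations, all plain CSV:

* BMI-for-age and height-for-age LMS tables with columns
  ``sex, age_months, L, M, S`` — the standard growth-chart
  parameterization (Box-Cox power L, median M, coefficient of variation
  S). Rows per sex must be sorted strictly increasing in age; L, M, S
  are interpolated linearly in age between bracketing rows.
* A blood-pressure coefficient table with columns
  ``sex, measure, intercept, a1..a4, h1..h4, sd``: the expected pressure
  for a child is ``intercept + sum_j a_j (age - 10)^j + sum_k h_k z^k``
  where z is the height-for-age z-score, and the percentile is the
  normal CDF of ``(observed - expected)/sd``. This is the functional
  form of the pediatric blood-pressure task-force references.
* A neck-circumference 95th-percentile table with columns
  ``sex, age_years, p95_cm``, looked up at the nearest integer age.

The bundled default tables (``data/*_synthetic.csv``) are synthetic
references with realistic magnitudes for ages 9-18; any table with the
same schema can be substituted.
"""

from __future__ import annotations

import math
import weakref
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .cohort import SubjectRecord

__all__ = [
    "ReferenceSet",
    "AnthropometricFlags",
    "ReferenceRangeError",
    "load_reference_set",
    "compute_bmi",
    "lms_zscore",
    "lms_inverse",
    "interpolate_lms",
    "bmi_percentile",
    "height_zscore",
    "expected_bp",
    "bp_percentile",
    "neck_p95",
    "anthropometric_flags",
]

_PCT_EPS = 1e-12  # keeps reported percentiles strictly inside (0, 100)


class ReferenceRangeError(ValueError):
    """Raised when a lookup falls outside a reference table's coverage."""


@dataclass
class ReferenceSet:
    """The three reference tables plus the height-for-age LMS table the
    blood-pressure model needs."""

    bmi_lms: pd.DataFrame
    height_lms: pd.DataFrame
    bp_coefficients: pd.DataFrame
    neck_p95: pd.DataFrame


@dataclass(frozen=True)
class AnthropometricFlags:
    """Computed percentiles and the three anthropometric score items.

    ``bp_flag`` uses the max of the systolic and diastolic percentiles
    with the >= 95 rule; ``bmi_flag`` is strict (> cut); ``neck_flag``
    is strict (> tabulated 95th percentile).
    """

    bmi: float
    bmi_percentile: float
    bmi_flag: bool
    systolic_percentile: float
    diastolic_percentile: float
    bp_percentile_max: float
    bp_flag: bool
    neck_flag: bool
    bmi_cut: float = 95.0


def load_reference_set(directory: str | Path | None = None) -> ReferenceSet:
    """Load a reference set from a directory of CSVs, or the bundled
    synthetic defaults when ``directory`` is None.

    Expected file names: ``bmi_lms*.csv``, ``height_lms*.csv``,
    ``bp_coefficients*.csv``, ``neck_p95*.csv`` (first glob match wins).
    """
    if directory is None:
        base = resources.files("stopbang").joinpath("data")
        read = lambda stem: pd.read_csv(str(base.joinpath(f"{stem}_synthetic.csv")))
        return ReferenceSet(
            bmi_lms=read("bmi_lms"),
            height_lms=read("height_lms"),
            bp_coefficients=read("bp_coefficients"),
            neck_p95=read("neck_p95"),
        )
    directory = Path(directory)

    def find(stem: str) -> pd.DataFrame:
        matches = sorted(directory.glob(f"{stem}*.csv"))
        if not matches:
            raise FileNotFoundError(f"no {stem}*.csv in {directory}")
        return pd.read_csv(matches[0])

    return ReferenceSet(
        bmi_lms=find("bmi_lms"),
        height_lms=find("height_lms"),
        bp_coefficients=find("bp_coefficients"),
        neck_p95=find("neck_p95"),
    )


def compute_bmi(weight: float, height: float) -> float:
    """Body mass index: weight in kg over squared height in metres."""
    if weight <= 0:
        raise ValueError(f"weight must be > 0, got {weight}")
    if height <= 0:
        raise ValueError(f"height must be > 0, got {height}")
    return weight / (height / 100.0) ** 2


def lms_zscore(x: float, L: float, M: float, S: float) -> float:
    """Box-Cox (LMS) z-score of measurement ``x`` against median M,
    coefficient of variation S and power L; the L=0 log-normal limit is
    taken for |L| below 1e-7."""
    if x <= 0 or M <= 0 or S <= 0:
        raise ValueError("x, M and S must all be > 0")
    if abs(L) < 1e-7:
        return math.log(x / M) / S
    return ((x / M) ** L - 1.0) / (L * S)


def lms_inverse(z: float, L: float, M: float, S: float) -> float:
    """Measurement whose LMS z-score is ``z`` (inverse of :func:`lms_zscore`).

    Returns NaN when ``z`` falls outside the Box-Cox support
    (``1 + L*S*z <= 0``), where no positive measurement has that z-score.
    """
    if M <= 0 or S <= 0:
        raise ValueError("M and S must be > 0")
    if abs(L) < 1e-7:
        return M * math.exp(S * z)
    base = 1.0 + L * S * z
    if base <= 0.0:
        return math.nan
    return M * base ** (1.0 / L)


def _percentile_from_z(z: float) -> float:
    return float(np.clip(ndtr(z) * 100.0, _PCT_EPS, 100.0 - _PCT_EPS))


# Per-(table, sex) numpy column cache; the weakref guards against a
# recycled id() after the original table is garbage-collected.
_column_cache: dict[tuple, tuple] = {}


def _sex_columns(table: pd.DataFrame, sex: str, columns: tuple[str, ...]) -> tuple[np.ndarray, ...]:
    key = (id(table), sex, columns)
    hit = _column_cache.get(key)
    if hit is not None and hit[0]() is table:
        return hit[1]
    sub = table[table["sex"] == sex]
    if sub.empty:
        raise ReferenceRangeError(f"no reference rows for sex {sex!r}")
    arrays = tuple(sub[c].to_numpy(dtype=float) for c in columns)
    _column_cache[key] = (weakref.ref(table), arrays)
    return arrays


def interpolate_lms(table: pd.DataFrame, sex: str, age_months: float) -> tuple[float, float, float]:
    """Linearly interpolate (L, M, S) in age for one sex.

    Ages outside the tabulated range raise :class:`ReferenceRangeError`
    naming the supported range.
    """
    ages, Ls, Ms, Ss = _sex_columns(table, sex, ("age_months", "L", "M", "S"))
    if not (ages[0] <= age_months <= ages[-1]):
        raise ReferenceRangeError(
            f"age {age_months:.1f} months outside reference range "
            f"[{ages[0]:.0f}, {ages[-1]:.0f}] for sex {sex!r}"
        )
    L = float(np.interp(age_months, ages, Ls))
    M = float(np.interp(age_months, ages, Ms))
    S = float(np.interp(age_months, ages, Ss))
    return L, M, S


def bmi_percentile(bmi: float, sex: str, age_months: float, table: pd.DataFrame) -> float:
    """BMI-for-age percentile via the LMS table (0-100, open interval)."""
    L, M, S = interpolate_lms(table, sex, age_months)
    return _percentile_from_z(lms_zscore(bmi, L, M, S))


def height_zscore(height: float, sex: str, age_months: float, table: pd.DataFrame) -> float:
    """Height-for-age z-score via the height LMS table."""
    L, M, S = interpolate_lms(table, sex, age_months)
    return lms_zscore(height, L, M, S)


def _bp_row(coeffs: pd.DataFrame, sex: str, measure: str) -> tuple:
    key = (id(coeffs), sex, measure)
    hit = _column_cache.get(key)
    if hit is not None and hit[0]() is coeffs:
        return hit[1]
    sub = coeffs[(coeffs["sex"] == sex) & (coeffs["measure"] == measure)]
    if sub.empty:
        raise ReferenceRangeError(f"no blood-pressure coefficients for ({sex}, {measure})")
    row = sub.iloc[0]
    values = (
        float(row["intercept"]),
        tuple(float(row[f"a{j}"]) for j in range(1, 5)),
        tuple(float(row[f"h{j}"]) for j in range(1, 5)),
        float(row["sd"]),
    )
    _column_cache[key] = (weakref.ref(coeffs), values)
    return values


def expected_bp(
    sex: str, measure: str, age_years: float, height_z: float, coeffs: pd.DataFrame
) -> tuple[float, float]:
    """Expected blood pressure (mmHg) and residual SD for a child of the
    given age and height-for-age z-score."""
    intercept, age_coeffs, height_coeffs, sd = _bp_row(coeffs, sex, measure)
    a = age_years - 10.0
    expected = intercept
    for j in range(1, 5):
        expected += age_coeffs[j - 1] * a**j
        expected += height_coeffs[j - 1] * height_z**j
    return expected, sd


def bp_percentile(
    observed: float,
    sex: str,
    measure: str,
    age_years: float,
    height: float,
    height_lms: pd.DataFrame,
    coeffs: pd.DataFrame,
) -> float:
    """Blood-pressure percentile for height, age and sex (0-100).

    The observed value should be the averaged 2nd/3rd readings, applied
    at ingestion.
    """
    z_height = height_zscore(height, sex, age_years * 12.0, height_lms)
    expected, sd = expected_bp(sex, measure, age_years, z_height, coeffs)
    return _percentile_from_z((observed - expected) / sd)


def neck_p95(sex: str, age_years: float, table: pd.DataFrame) -> float:
    """95th-percentile neck circumference (cm) at the nearest integer age."""
    age_int = math.floor(age_years + 0.5)
    ages, p95s = _sex_columns(table, sex, ("age_years", "p95_cm"))
    matches = np.nonzero(ages == age_int)[0]
    if matches.size == 0:
        raise ReferenceRangeError(
            f"no neck reference for ({sex}, age {age_int}); "
            f"covered ages {int(ages.min())}-{int(ages.max())}"
        )
    return float(p95s[matches[0]])


def anthropometric_flags(
    record: SubjectRecord, refs: ReferenceSet, bmi_cut: float = 95.0
) -> AnthropometricFlags:
    """Compute the three anthropometric score items for one child.

    ``bmi_cut`` is the BMI percentile cut point (90/95/99 in the
    sensitivity analyses; strict > rule). Requires a record complete for
    anthropometrics.
    """
    required = ("age", "sex", "height", "weight", "systolic_bp", "diastolic_bp", "neck_circumference")
    missing = [name for name in required if getattr(record, name) is None]
    if missing:
        raise ValueError(f"subject {record.subject_id}: incomplete anthropometrics: {missing}")
    bmi = compute_bmi(record.weight, record.height)
    bmi_pct = bmi_percentile(bmi, record.sex, record.age * 12.0, refs.bmi_lms)
    z_height = height_zscore(record.height, record.sex, record.age * 12.0, refs.height_lms)
    sys_exp, sys_sd = expected_bp(
        record.sex, "systolic", record.age, z_height, refs.bp_coefficients
    )
    dia_exp, dia_sd = expected_bp(
        record.sex, "diastolic", record.age, z_height, refs.bp_coefficients
    )
    sys_pct = _percentile_from_z((record.systolic_bp - sys_exp) / sys_sd)
    dia_pct = _percentile_from_z((record.diastolic_bp - dia_exp) / dia_sd)
    bp_max = max(sys_pct, dia_pct)
    neck_cut = neck_p95(record.sex, record.age, refs.neck_p95)
    return AnthropometricFlags(
        bmi=bmi,
        bmi_percentile=bmi_pct,
        bmi_flag=bmi_pct > bmi_cut,
        systolic_percentile=sys_pct,
        diastolic_percentile=dia_pct,
        bp_percentile_max=bp_max,
        bp_flag=bp_max >= 95.0,
        neck_flag=record.neck_circumference > neck_cut,
        bmi_cut=bmi_cut,
    )


def percentile_to_z(percentile: float) -> float:
    """Standard-normal quantile of a percentile in (0, 100)."""
    if not 0.0 < percentile < 100.0:
        raise ValueError("percentile must be strictly inside (0, 100)")
    return float(ndtri(percentile / 100.0))
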