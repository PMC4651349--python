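"""Cohort data model: subject records, CSV interchange, completeness
filtering, OSA labelling from the apnea-hypopnea index, and stratification.

A cohort is a list of :class:`SubjectRecord`, one per child, carrying
demographics, anthropometrics measured at the home visit, the self-assessed
sexual maturity rating (SMR, Tanner stage 1-5), the apnea-hypopnea index
(AHI, events per hour of sleep from polysomnography) and the four ordinal
questionnaire items answered separately by the parent and by the child.

The canonical interchange format is a UTF-8 CSV with a header row and the
column dictionary in :data:`CSV_COLUMNS`. Blood pressure columns are
expected to already be the average of the 2nd and 3rd seated readings;
that averaging happens at measurement/ingestion time, not here.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ResponseLevel",
    "SubjectRecord",
    "OsaLabel",
    "CohortParseError",
    "REPORTERS",
    "QUESTIONNAIRE_ITEMS",
    "CSV_COLUMNS",
    "parse_response",
    "read_cohort_csv",
    "read_cohort_sav",
    "write_cohort_csv",
    "filter_complete",
    "classify_osa",
    "stratify",
    "age_group",
    "smr_group",
]

REPORTERS = ("parent", "child")
QUESTIONNAIRE_ITEMS = ("snoring", "tired", "observed_apnea", "academic")

SEXES = ("male", "female")
ETHNICITIES = ("caucasian", "hispanic", "other")

#: sanity window for age at the home visit, in years
AGE_WINDOW = (5.0, 25.0)


class ResponseLevel(str, Enum):
    """The six admissible ordinal answers to a questionnaire item."""

    DONT_KNOW = "dont_know"
    NEVER = "never"
    RARELY = "rarely"
    OCCASIONALLY = "occasionally"
    FREQUENTLY = "frequently"
    ALMOST_ALWAYS = "almost_always"


_RESPONSE_ALIASES = {
    "dont_know": ResponseLevel.DONT_KNOW,
    "don't know": ResponseLevel.DONT_KNOW,
    "dont know": ResponseLevel.DONT_KNOW,
    "unknown": ResponseLevel.DONT_KNOW,
    "never": ResponseLevel.NEVER,
    "rarely": ResponseLevel.RARELY,
    "occasionally": ResponseLevel.OCCASIONALLY,
    "frequently": ResponseLevel.FREQUENTLY,
    "almost_always": ResponseLevel.ALMOST_ALWAYS,
    "almost always": ResponseLevel.ALMOST_ALWAYS,
}


class CohortParseError(ValueError):
    """Raised when a cohort CSV cell cannot be interpreted."""


def parse_response(text: str | None) -> ResponseLevel | None:
    """Normalize one questionnaire cell to a :class:`ResponseLevel`.

    Matching is case-insensitive after trimming; empty cells are missing
    (``None``). Unknown strings raise, listing the admissible levels.
    """
    if text is None:
        return None
    key = text.strip().lower().replace("-", " ")
    if key == "":
        return None
    key = _RESPONSE_ALIASES.get(key) or _RESPONSE_ALIASES.get(key.replace(" ", "_"))
    if key is None:
        admissible = ", ".join(level.value for level in ResponseLevel)
        raise CohortParseError(
            f"unknown response level {text!r}; admissible levels are: {admissible}"
        )
    return key


@dataclass
class SubjectRecord:
    """One child's measurements and questionnaire answers.

    ``responses`` maps reporter -> item -> level; missing answers are
    ``None``. ``systolic_bp``/``diastolic_bp`` are the averaged readings
    in mmHg, ``height`` cm, ``weight`` kg, ``neck_circumference`` cm,
    ``ahi`` events/hour.
    """

    subject_id: str
    age: float | None = None
    sex: str | None = None
    ethnicity: str | None = None
    height: float | None = None
    weight: float | None = None
    systolic_bp: float | None = None
    diastolic_bp: float | None = None
    neck_circumference: float | None = None
    smr: int | None = None
    ahi: float | None = None
    responses: dict[str, dict[str, ResponseLevel | None]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.age is not None and not (AGE_WINDOW[0] <= self.age <= AGE_WINDOW[1]):
            raise ValueError(
                f"subject {self.subject_id}: age {self.age} outside sanity window {AGE_WINDOW}"
            )
        for name in ("height", "weight", "neck_circumference"):
            value = getattr(self, name)
            if value is not None and value <= 0:
                raise ValueError(f"subject {self.subject_id}: {name} must be > 0, got {value}")
        if self.ahi is not None and self.ahi < 0:
            raise ValueError(f"subject {self.subject_id}: ahi must be >= 0, got {self.ahi}")
        if self.smr is not None and self.smr not in (1, 2, 3, 4, 5):
            raise ValueError(f"subject {self.subject_id}: smr must be in 1..5, got {self.smr}")
        if self.sex is not None and self.sex not in SEXES:
            raise ValueError(f"subject {self.subject_id}: sex must be one of {SEXES}")
        if self.ethnicity is not None and self.ethnicity not in ETHNICITIES:
            raise ValueError(f"subject {self.subject_id}: ethnicity must be one of {ETHNICITIES}")
        for reporter in REPORTERS:
            self.responses.setdefault(reporter, {})
            for item in QUESTIONNAIRE_ITEMS:
                self.responses[reporter].setdefault(item, None)

    def response(self, reporter: str, item: str) -> ResponseLevel | None:
        return self.responses.get(reporter, {}).get(item)


@dataclass(frozen=True)
class OsaLabel:
    """Dichotomous OSA status with the AHI threshold that produced it."""

    is_osa: bool
    threshold: float = 1.5


#: canonical cohort CSV columns, in file order
CSV_COLUMNS = (
    "subject_id",
    "age_years",
    "sex",
    "ethnicity",
    "height_cm",
    "weight_kg",
    "sbp_mmhg",
    "dbp_mmhg",
    "neck_cm",
    "smr",
    "ahi",
    "parent_snoring",
    "parent_tired",
    "parent_observed",
    "parent_academic",
    "child_snoring",
    "child_tired",
    "child_observed",
    "child_academic",
)

_NUMERIC_FIELDS = {
    "age_years": "age",
    "height_cm": "height",
    "weight_kg": "weight",
    "sbp_mmhg": "systolic_bp",
    "dbp_mmhg": "diastolic_bp",
    "neck_cm": "neck_circumference",
    "ahi": "ahi",
}

_ITEM_COLUMN = {
    ("parent", "snoring"): "parent_snoring",
    ("parent", "tired"): "parent_tired",
    ("parent", "observed_apnea"): "parent_observed",
    ("parent", "academic"): "parent_academic",
    ("child", "snoring"): "child_snoring",
    ("child", "tired"): "child_tired",
    ("child", "observed_apnea"): "child_observed",
    ("child", "academic"): "child_academic",
}


def _cell(row: Mapping[str, str], column: str) -> str | None:
    value = row.get(column)
    if value is None or value.strip() == "":
        return None
    return value.strip()


def read_cohort_csv(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> list[SubjectRecord]:
    """Read a cohort CSV into subject records.

    ``column_map`` optionally maps canonical column names (see
    :data:`CSV_COLUMNS`) to the names actually used in the file. Missing
    cells stay missing; malformed cells raise :class:`CohortParseError`
    naming the row and column.
    """
    path = Path(path)
    rename = dict(column_map or {})

    def col(name: str) -> str:
        return rename.get(name, name)

    records: list[SubjectRecord] = []
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            raise CohortParseError(f"{path}: empty file, header row required")
        missing_cols = [c for c in CSV_COLUMNS if col(c) not in reader.fieldnames]
        if missing_cols:
            raise CohortParseError(f"{path}: missing columns {missing_cols}")
        for line_no, row in enumerate(reader, start=2):
            try:
                kwargs: dict = {"subject_id": _cell(row, col("subject_id")) or f"row{line_no}"}
                for column, attr in _NUMERIC_FIELDS.items():
                    raw = _cell(row, col(column))
                    if raw is not None:
                        try:
                            kwargs[attr] = float(raw)
                        except ValueError as exc:
                            raise CohortParseError(
                                f"row {line_no}, column {col(column)}: not a number: {raw!r}"
                            ) from exc
                raw = _cell(row, col("smr"))
                if raw is not None:
                    try:
                        kwargs["smr"] = int(float(raw))
                    except ValueError as exc:
                        raise CohortParseError(
                            f"row {line_no}, column {col('smr')}: not an integer: {raw!r}"
                        ) from exc
                raw = _cell(row, col("sex"))
                if raw is not None:
                    kwargs["sex"] = raw.lower()
                raw = _cell(row, col("ethnicity"))
                if raw is not None:
                    kwargs["ethnicity"] = raw.lower()
                responses: dict[str, dict[str, ResponseLevel | None]] = {}
                for (reporter, item), column in _ITEM_COLUMN.items():
                    try:
                        level = parse_response(_cell(row, col(column)))
                    except CohortParseError as exc:
                        raise CohortParseError(
                            f"row {line_no}, column {col(column)}: {exc}"
                        ) from exc
                    responses.setdefault(reporter, {})[item] = level
                kwargs["responses"] = responses
                records.append(SubjectRecord(**kwargs))
            except ValueError as exc:
                if isinstance(exc, CohortParseError):
                    raise
                raise CohortParseError(f"row {line_no}: {exc}") from exc
    return records


def read_cohort_sav(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> list[SubjectRecord]:
    """Optional reader for SPSS (.sav) cohort files.

    Requires the ``pyreadstat`` extra. The file is converted to the
    canonical CSV column dictionary (via ``column_map`` if its variable
    names differ) and parsed with the same validation as
    :func:`read_cohort_csv`.
    """
    try:
        import pyreadstat
    except ImportError as exc:
        raise ImportError(
            "reading .sav files requires the optional dependency pyreadstat "
            "(pip install teen-stopbang[sav])"
        ) from exc
    import tempfile

    frame, _meta = pyreadstat.read_sav(str(path))
    with tempfile.NamedTemporaryFile("w", suffix=".csv", delete=False) as handle:
        frame.to_csv(handle, index=False)
        tmp_path = handle.name
    try:
        return read_cohort_csv(tmp_path, column_map=column_map)
    finally:
        Path(tmp_path).unlink(missing_ok=True)


def write_cohort_csv(records: Iterable[SubjectRecord], path: str | Path) -> None:
    """Write records to the canonical cohort CSV (round-trips with
    :func:`read_cohort_csv`)."""
    path = Path(path)

    def fmt(value) -> str:
        if value is None:
            return ""
        if isinstance(value, float):
            return repr(value)
        return str(value)

    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(CSV_COLUMNS)
        for rec in records:
            row = [
                rec.subject_id,
                fmt(rec.age),
                fmt(rec.sex),
                fmt(rec.ethnicity),
                fmt(rec.height),
                fmt(rec.weight),
                fmt(rec.systolic_bp),
                fmt(rec.diastolic_bp),
                fmt(rec.neck_circumference),
                fmt(rec.smr),
                fmt(rec.ahi),
            ]
            for (reporter, item), _column in _ITEM_COLUMN.items():
                level = rec.response(reporter, item)
                row.append("" if level is None else level.value)
            writer.writerow(row)


_ANTHROPOMETRIC_FIELDS = (
    "age",
    "sex",
    "height",
    "weight",
    "systolic_bp",
    "diastolic_bp",
    "neck_circumference",
)


def filter_complete(
    records: Sequence[SubjectRecord], reporter: str
) -> tuple[list[SubjectRecord], list[tuple[SubjectRecord, list[str]]]]:
    """Partition records into analysis-ready and dropped-with-reasons.

    A record is kept when every anthropometric field, all four of the
    given reporter's questionnaire items, and the AHI are present. The
    two outputs always partition the input.
    """
    if reporter not in REPORTERS:
        raise ValueError(f"reporter must be one of {REPORTERS}, got {reporter!r}")
    kept: list[SubjectRecord] = []
    dropped: list[tuple[SubjectRecord, list[str]]] = []
    for rec in records:
        reasons = [name for name in _ANTHROPOMETRIC_FIELDS if getattr(rec, name) is None]
        reasons += [
            f"{reporter}_{item}"
            for item in QUESTIONNAIRE_ITEMS
            if rec.response(reporter, item) is None
        ]
        if rec.ahi is None:
            reasons.append("ahi")
        if reasons:
            dropped.append((rec, reasons))
        else:
            kept.append(rec)
    return kept, dropped


def classify_osa(ahi: float, threshold: float = 1.5) -> OsaLabel:
    """Label OSA from the apnea-hypopnea index: positive iff ahi >= threshold."""
    if ahi < 0:
        raise ValueError(f"ahi must be >= 0, got {ahi}")
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    return OsaLabel(is_osa=ahi >= threshold, threshold=threshold)


def age_group(age: float) -> str:
    """Preteen below 13 years (decimal age), teen at 13 or older."""
    return "teen" if age >= 13.0 else "preteen"


def smr_group(smr: int | None) -> str:
    """Pubertal strata: SMR >= 4 is the later-puberty split; missing SMR
    falls in an explicit "unknown" stratum."""
    if smr is None:
        return "unknown"
    return "high" if smr >= 4 else "low"


def stratify(
    records: Sequence[SubjectRecord], by: str
) -> dict[str, list[SubjectRecord]]:
    """Partition records by age group or SMR group.

    ``by="age_group"`` yields preteen (< 13 y) / teen (>= 13 y);
    ``by="smr_group"`` yields low (SMR < 4) / high (SMR >= 4) / unknown.
    Only non-empty strata appear; the strata partition the input.
    """
    if by == "age_group":
        keyer = lambda rec: age_group(rec.age)
    elif by == "smr_group":
        keyer = lambda rec: smr_group(rec.smr)
    else:
        raise ValueError(f"by must be 'age_group' or 'smr_group', got {by!r}")
    out: dict[str, list[SubjectRecord]] = {}
    for rec in records:
        out.setdefault(keyer(rec), []).append(rec)
    return out


def copy_record(record: SubjectRecord, **changes) -> SubjectRecord:
    """Return a modified copy (responses deep-copied)."""
    responses = {rep: dict(items) for rep, items in record.responses.items()}
    return replace(record, responses=changes.pop("responses", responses), **changes)
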