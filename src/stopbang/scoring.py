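"""Teen STOP-Bang scoring.

The instrument counts eight yes/no items: Snoring, Tiredness, Observed
apnea, blood Pressure >= 95th percentile, BMI > 95th percentile, Academic
problems (the pediatric substitution for the adult tool's age item), Neck
circumference > 95th percentile for age, and male Gender. The four
questionnaire items are answered on a six-level ordinal scale and
collapsed to positive iff the answer is "frequently" or "almost always";
the anthropometric items come from measured values against pediatric
references. The score is the count of positive items (0-8). The
"STOP-Bag" variant drops the neck item (0-7). A score at or above the
risk threshold (default 3) marks elevated OSA risk.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .cohort import QUESTIONNAIRE_ITEMS, REPORTERS, ResponseLevel, SubjectRecord
from .reference import AnthropometricFlags, ReferenceSet, anthropometric_flags

__all__ = [
    "STOP_BANG_ITEMS",
    "STOP_BAG_ITEMS",
    "VARIANTS",
    "ScoreResult",
    "collapse_response",
    "score_subject",
    "score_cohort",
    "classify_risk",
]

#: item order of the full instrument; the neck-free variant drops "neck"
STOP_BANG_ITEMS = ("snoring", "tired", "observed_apnea", "bp", "bmi", "academic", "neck", "male")
STOP_BAG_ITEMS = tuple(item for item in STOP_BANG_ITEMS if item != "neck")
VARIANTS = {"stop_bang": STOP_BANG_ITEMS, "stop_bag": STOP_BAG_ITEMS}

_POSITIVE_LEVELS = frozenset({ResponseLevel.FREQUENTLY, ResponseLevel.ALMOST_ALWAYS})


@dataclass(frozen=True)
class ScoreResult:
    """Per-item positivity and the total count for one subject/reporter."""

    subject_id: str
    reporter: str
    variant: str
    item_flags: dict[str, bool]
    total: int


def collapse_response(level: ResponseLevel) -> bool:
    """Dichotomize an ordinal answer: positive iff frequently or almost
    always; don't-know, never, rarely and occasionally are all negative."""
    return ResponseLevel(level) in _POSITIVE_LEVELS


def score_subject(
    record: SubjectRecord,
    flags: AnthropometricFlags,
    reporter: str = "parent",
    variant: str = "stop_bang",
) -> ScoreResult:
    """Score one child from the given reporter's questionnaire plus the
    measured anthropometric flags.

    Both reporters share the same measured flags and sex; only the four
    questionnaire items differ by reporter. A missing questionnaire item
    raises, naming the item.
    """
    if reporter not in REPORTERS:
        raise ValueError(f"reporter must be one of {REPORTERS}, got {reporter!r}")
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {tuple(VARIANTS)}, got {variant!r}")
    item_flags: dict[str, bool] = {}
    for item in VARIANTS[variant]:
        if item in QUESTIONNAIRE_ITEMS:
            level = record.response(reporter, item)
            if level is None:
                raise ValueError(
                    f"subject {record.subject_id}: missing {reporter} response for item {item!r}"
                )
            item_flags[item] = collapse_response(level)
        elif item == "bp":
            item_flags[item] = flags.bp_flag
        elif item == "bmi":
            item_flags[item] = flags.bmi_flag
        elif item == "neck":
            item_flags[item] = flags.neck_flag
        elif item == "male":
            if record.sex is None:
                raise ValueError(f"subject {record.subject_id}: missing sex")
            item_flags[item] = record.sex == "male"
    return ScoreResult(
        subject_id=record.subject_id,
        reporter=reporter,
        variant=variant,
        item_flags=item_flags,
        total=sum(item_flags.values()),
    )


def score_cohort(
    records: Sequence[SubjectRecord],
    refs: ReferenceSet,
    reporter: str = "parent",
    variant: str = "stop_bang",
    bmi_cut: float = 95.0,
) -> pd.DataFrame:
    """Score every record; returns one row per subject with the item
    booleans, the total, age, SMR and AHI (for downstream labelling)."""
    rows = []
    for rec in records:
        flags = anthropometric_flags(rec, refs, bmi_cut=bmi_cut)
        result = score_subject(rec, flags, reporter=reporter, variant=variant)
        row = {"subject_id": rec.subject_id, "reporter": reporter, "variant": variant}
        row.update(result.item_flags)
        row["total"] = result.total
        row["age"] = rec.age
        row["smr"] = rec.smr
        row["ahi"] = rec.ahi
        rows.append(row)
    return pd.DataFrame(rows)


def classify_risk(total: int, threshold: int = 3) -> str:
    """Risk stratum from the total score: "elevated" iff total >= threshold.

    A low score argues against OSA (the instrument's intended use is
    ruling out the need for polysomnography).
    """
    if not 1 <= threshold <= 8:
        raise ValueError(f"threshold must be in [1, 8], got {threshold}")
    return "elevated" if total >= threshold else "low"
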