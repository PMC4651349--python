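"""Synthetic cohort generation.

Emulates the structure of the community adolescent sleep cohort the
instrument was developed on: n = 312 children aged 9-17.6, OSA
prevalence 0.08 (apnea-hypopnea index >= 1.5 events/hour), 6-level
ordinal questionnaire answers from parent and child, measured
anthropometrics, and self-reported sexual maturity rating (missing for a
small fraction, 21/312 by default).

Generative model: OSA status is Bernoulli(prevalence); given status, the
eight score items are independent Bernoulli draws (exchangeable within
class). The default per-class item probabilities are calibrated so a
parent-reported score >= 3 has sensitivity 0.64 and specificity 0.82 —
the instrument's headline operating point. AHI is drawn log-normally
with medians ~0.2 (healthy, truncated below the diagnostic threshold)
and ~2.2 (OSA). Child questionnaire answers copy the parent's with
probability ``reporter_agreement``, else are redrawn from the same
class-conditional law. Anthropometric measurements are back-solved from
the intended flags: values are placed a fixed distance above or below
the relevant reference cut so the pediatric-reference module reproduces
the intended item flags exactly (flags, not raw measurement
distributions, drive the score).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import brentq
from scipy.stats import binom

from .cohort import QUESTIONNAIRE_ITEMS, ResponseLevel, SubjectRecord, classify_osa
from .reference import ReferenceSet, load_reference_set
from .scoring import STOP_BANG_ITEMS

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "calibrate_items",
    "simulate_cohort",
    "simulate_scores",
]

_POSITIVE_RESPONSES = (ResponseLevel.FREQUENTLY, ResponseLevel.ALMOST_ALWAYS)
_NEGATIVE_RESPONSES = (
    ResponseLevel.DONT_KNOW,
    ResponseLevel.NEVER,
    ResponseLevel.RARELY,
    ResponseLevel.OCCASIONALLY,
)
_NEGATIVE_WEIGHTS = (0.05, 0.45, 0.30, 0.20)


def calibrate_items(
    target_sens: float,
    target_spec: float,
    threshold: int = 3,
    n_items: int = 8,
) -> tuple[dict[str, float], dict[str, float], tuple[float, float]]:
    """Per-class item probabilities hitting a target operating point.

    With exchangeable Bernoulli(p) items the score is Binomial(n_items,
    p), so we invert the binomial survival function: find p_osa with
    P(score >= threshold | OSA) = target_sens and p_healthy with
    P(score >= threshold | healthy) = 1 - target_spec. Returns the two
    item->probability maps and the achieved (sens, spec) (exact to the
    root-finder tolerance). Unreachable targets raise with the nearest
    achievable values.
    """
    if not 1 <= threshold <= n_items:
        raise ValueError(
            f"threshold {threshold} unreachable with {n_items} items; "
            f"achievable tail range is (0, 1) for thresholds 1..{n_items}"
        )

    def solve(target_tail: float) -> float:
        if not 0.0 <= target_tail <= 1.0:
            raise ValueError(f"target tail probability {target_tail} outside [0, 1]")
        if target_tail == 0.0:
            return 0.0
        if target_tail == 1.0:
            return 1.0
        return brentq(
            lambda p: binom.sf(threshold - 1, n_items, p) - target_tail,
            0.0, 1.0, xtol=1e-12,
        )

    p_osa = solve(target_sens)
    p_healthy = solve(1.0 - target_spec)
    achieved_sens = float(binom.sf(threshold - 1, n_items, p_osa))
    achieved_spec = 1.0 - float(binom.sf(threshold - 1, n_items, p_healthy))
    osa_map = {item: p_osa for item in STOP_BANG_ITEMS}
    healthy_map = {item: p_healthy for item in STOP_BANG_ITEMS}
    return osa_map, healthy_map, (achieved_sens, achieved_spec)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults are the development cohort's: n = 312, prevalence 0.08,
    ages 9-17.6, item probabilities calibrated to sensitivity 0.64 /
    specificity 0.82 at score threshold 3, SMR missing for 21/312.
    """

    n: int = 312
    prevalence: float = 0.08
    seed: int = 0
    age_range: tuple[float, float] = (9.0, 17.6)
    sex_ratio: float = 0.5
    item_prob_given_osa: Mapping[str, float] | None = None
    item_prob_given_healthy: Mapping[str, float] | None = None
    reporter_agreement: float = 0.7
    smr_age_slope: float = 1.5
    smr_midpoint_age: float = 13.5
    smr_missing_rate: float = 21 / 312
    ahi_threshold: float = 1.5
    bmi_cut: float = 95.0
    target_sens: float = 0.64
    target_spec: float = 0.82
    score_threshold: int = 3

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError(f"n must be > 0, got {self.n}")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(f"prevalence must be in (0, 1), got {self.prevalence}")
        if self.item_prob_given_osa is None or self.item_prob_given_healthy is None:
            osa_map, healthy_map, _ = calibrate_items(
                self.target_sens, self.target_spec, self.score_threshold
            )
            if self.item_prob_given_osa is None:
                self.item_prob_given_osa = osa_map
            if self.item_prob_given_healthy is None:
                self.item_prob_given_healthy = healthy_map
        for probs in (self.item_prob_given_osa, self.item_prob_given_healthy):
            for item in STOP_BANG_ITEMS:
                p = probs.get(item, self.sex_ratio if item == "male" else None)
                if p is None or not 0.0 <= p <= 1.0:
                    raise ValueError(f"invalid probability for item {item!r}: {p}")
        for name in ("reporter_agreement", "smr_missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class SyntheticCohort:
    records: list[SubjectRecord]
    truth: dict[str, bool]
    config: SimulationConfig


def _item_prob_arrays(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    osa = np.array([config.item_prob_given_osa[i] for i in STOP_BANG_ITEMS])
    healthy = np.array([config.item_prob_given_healthy[i] for i in STOP_BANG_ITEMS])
    return osa, healthy


def simulate_scores(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fast path: draw (parent totals, child totals, OSA labels) from the
    item model alone, without building full subject records."""
    rng = rng or np.random.default_rng(config.seed)
    p_osa, p_healthy = _item_prob_arrays(config)
    status = rng.random(config.n) < config.prevalence
    probs = np.where(status[:, None], p_osa[None, :], p_healthy[None, :])
    parent_items = rng.random((config.n, len(STOP_BANG_ITEMS))) < probs
    redraw = rng.random((config.n, len(STOP_BANG_ITEMS))) >= config.reporter_agreement
    fresh = rng.random((config.n, len(STOP_BANG_ITEMS))) < probs
    child_items = np.where(redraw, fresh, parent_items)
    # the four non-questionnaire items are measured once, shared by reporters
    questionnaire = np.array([i in QUESTIONNAIRE_ITEMS for i in STOP_BANG_ITEMS])
    child_items[:, ~questionnaire] = parent_items[:, ~questionnaire]
    return parent_items.sum(axis=1), child_items.sum(axis=1), status


def _draw_ahi(rng: np.random.Generator, status: np.ndarray, threshold: float) -> np.ndarray:
    n = status.size
    healthy = np.exp(rng.normal(np.log(0.2), 0.8, size=n))
    healthy = np.minimum(healthy, threshold - 0.05)
    osa = threshold + np.exp(rng.normal(np.log(0.7), 0.8, size=n))
    return np.where(status, osa, healthy)


def _interp_by_sex(
    table, value_col: str, sex: np.ndarray, age_months: np.ndarray, age_col: str = "age_months"
) -> np.ndarray:
    out = np.empty_like(age_months, dtype=float)
    for s in ("male", "female"):
        mask = sex == s
        if not mask.any():
            continue
        sub = table[table["sex"] == s]
        out[mask] = np.interp(
            age_months[mask],
            sub[age_col].to_numpy(dtype=float),
            sub[value_col].to_numpy(dtype=float),
        )
    return out


def simulate_cohort(
    config: SimulationConfig, refs: ReferenceSet | None = None
) -> SyntheticCohort:
    """Generate a full synthetic cohort of subject records.

    Deterministic under a fixed ``config.seed``. Anthropometrics are
    back-solved against ``refs`` (bundled defaults when None) so that
    recomputing flags from the records reproduces the generated item
    flags exactly, and the truth labels agree with ``classify_osa`` on
    the generated AHI in every record.
    """
    refs = refs or load_reference_set()
    rng = np.random.default_rng(config.seed)
    n = config.n
    items = STOP_BANG_ITEMS
    idx = {item: k for k, item in enumerate(items)}

    p_osa, p_healthy = _item_prob_arrays(config)
    status = rng.random(n) < config.prevalence
    probs = np.where(status[:, None], p_osa[None, :], p_healthy[None, :])
    parent_items = rng.random((n, len(items))) < probs
    redraw = rng.random((n, len(items))) >= config.reporter_agreement
    fresh = rng.random((n, len(items))) < probs
    child_items = np.where(redraw, fresh, parent_items)

    sex = np.where(parent_items[:, idx["male"]], "male", "female")
    age = rng.uniform(config.age_range[0], config.age_range[1], size=n)
    age_months = age * 12.0
    ahi = _draw_ahi(rng, status, config.ahi_threshold)

    # SMR: later puberty more likely with age, missing for a small fraction
    p_high = 1.0 / (1.0 + np.exp(-config.smr_age_slope * (age - config.smr_midpoint_age)))
    smr_high = rng.random(n) < p_high
    smr = np.where(smr_high, rng.integers(4, 6, size=n), rng.integers(1, 4, size=n))
    smr_missing = rng.random(n) < config.smr_missing_rate

    # height at the reference median (height-for-age z = 0)
    height = _interp_by_sex(refs.height_lms, "M", sex, age_months)

    # BMI back-solved from a percentile clearly on the intended side of the cut
    from scipy.special import ndtri

    cut = config.bmi_cut
    pct = np.where(parent_items[:, idx["bmi"]], cut + 0.6 * (100.0 - cut), 0.6 * cut)
    z_bmi = ndtri(pct / 100.0)
    L = _interp_by_sex(refs.bmi_lms, "L", sex, age_months)
    M = _interp_by_sex(refs.bmi_lms, "M", sex, age_months)
    S = _interp_by_sex(refs.bmi_lms, "S", sex, age_months)
    with np.errstate(invalid="ignore"):
        bmi = np.where(
            np.abs(L) < 1e-7,
            M * np.exp(S * z_bmi),
            M * (1.0 + L * S * z_bmi) ** (1.0 / L),
        )
    weight = bmi * (height / 100.0) ** 2

    # blood pressure: systolic at expected + 1.8 SD when flagged (>= 95th),
    # at expected (50th) otherwise; diastolic always at expected
    a = age - 10.0
    sbp = np.zeros(n)
    dbp = np.zeros(n)
    for s in ("male", "female"):
        mask = sex == s
        if not mask.any():
            continue
        for measure, out in (("systolic", sbp), ("diastolic", dbp)):
            row = refs.bp_coefficients[
                (refs.bp_coefficients["sex"] == s)
                & (refs.bp_coefficients["measure"] == measure)
            ].iloc[0]
            expected = float(row["intercept"]) + sum(
                float(row[f"a{j}"]) * a[mask] ** j for j in range(1, 5)
            )
            if measure == "systolic":
                expected = expected + np.where(
                    parent_items[mask, idx["bp"]], 1.8 * float(row["sd"]), 0.0
                )
            out[mask] = expected

    # neck circumference just above/below the tabulated 95th percentile
    age_int = np.floor(age + 0.5)
    p95 = _interp_by_sex(refs.neck_p95, "p95_cm", sex, age_int, age_col="age_years")
    neck = np.where(parent_items[:, idx["neck"]], p95 + 1.0, p95 - 2.0)

    q_idx = [idx[item] for item in QUESTIONNAIRE_ITEMS]

    def draw_response(flag: bool) -> ResponseLevel:
        if flag:
            return _POSITIVE_RESPONSES[rng.integers(0, len(_POSITIVE_RESPONSES))]
        return _NEGATIVE_RESPONSES[rng.choice(len(_NEGATIVE_RESPONSES), p=_NEGATIVE_WEIGHTS)]

    records: list[SubjectRecord] = []
    truth: dict[str, bool] = {}
    width = len(str(n))
    for i in range(n):
        responses = {
            "parent": {
                item: draw_response(bool(parent_items[i, k]))
                for item, k in zip(QUESTIONNAIRE_ITEMS, q_idx)
            },
            "child": {
                item: draw_response(bool(child_items[i, k]))
                for item, k in zip(QUESTIONNAIRE_ITEMS, q_idx)
            },
        }
        subject_id = f"S{i + 1:0{width}d}"
        rec = SubjectRecord(
            subject_id=subject_id,
            age=float(age[i]),
            sex=str(sex[i]),
            ethnicity=("caucasian", "hispanic")[int(rng.random() < 0.36)],
            height=float(height[i]),
            weight=float(weight[i]),
            systolic_bp=float(sbp[i]),
            diastolic_bp=float(dbp[i]),
            neck_circumference=float(neck[i]),
            smr=None if smr_missing[i] else int(smr[i]),
            ahi=float(ahi[i]),
            responses=responses,
        )
        records.append(rec)
        truth[subject_id] = classify_osa(rec.ahi, config.ahi_threshold).is_osa
    return SyntheticCohort(records=records, truth=truth, config=config)
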