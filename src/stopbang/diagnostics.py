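"""Diagnostic test accuracy: 2x2 contingency tables at score thresholds
and the derived characteristics with 95% confidence intervals —
sensitivity, specificity, predictive values, likelihood ratios, and
prevalence-adjusted likelihood ratios.

A prevalence-adjusted likelihood ratio is the plain likelihood ratio
multiplied by the pre-test odds ``p/(1-p)``, i.e. the post-test odds of
disease after a positive (LR+[P]) or negative (LR-[P]) result. At a
cohort prevalence far from 0.5 — here OSA prevalence ~= 0.08 — the
unadjusted ratios overstate how much a positive result should move a
clinician, which is why the adjusted versions are reported alongside.

Confidence intervals: proportions use the Wilson score interval by
default (Clopper-Pearson selectable); likelihood ratios use the standard
log method, with a +0.5 continuity correction on all four cells (and a
flag) when a needed cell is zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ContingencyTable",
    "DiagnosticSummary",
    "build_contingency",
    "test_characteristics",
    "likelihood_ratios",
    "prevalence_adjusted_lrs",
    "proportion_ci",
    "lr_ci",
    "summarize_table",
    "summary_table",
    "round_half_up",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: test-positive/negative against diseased/non-diseased."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def diseased(self) -> int:
        return self.tp + self.fn

    @property
    def non_diseased(self) -> int:
        return self.fp + self.tn


@dataclass
class DiagnosticSummary:
    """One accuracy-panel row: characteristics with CIs at one threshold
    in one stratum. Undefined quantities (zero denominators) are None,
    with the reason recorded in ``notes``."""

    stratum: str
    threshold: int
    table: ContingencyTable
    prevalence: float
    sensitivity: float | None = None
    specificity: float | None = None
    ppv: float | None = None
    npv: float | None = None
    lr_pos: float | None = None
    lr_neg: float | None = None
    lr_pos_prev: float | None = None
    lr_neg_prev: float | None = None
    sensitivity_ci: tuple[float, float] | None = None
    specificity_ci: tuple[float, float] | None = None
    ppv_ci: tuple[float, float] | None = None
    npv_ci: tuple[float, float] | None = None
    lr_pos_ci: tuple[float, float] | None = None
    lr_neg_ci: tuple[float, float] | None = None
    lr_pos_prev_ci: tuple[float, float] | None = None
    lr_neg_prev_ci: tuple[float, float] | None = None
    notes: list[str] = field(default_factory=list)


def build_contingency(
    scores: Sequence[float], labels: Sequence[bool], threshold: int
) -> ContingencyTable:
    """Cross-tabulate score >= threshold against disease status."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.size == 0:
        raise ValueError("empty input")
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    positive = scores >= threshold
    return ContingencyTable(
        tp=int(np.sum(positive & labels)),
        fp=int(np.sum(positive & ~labels)),
        fn=int(np.sum(~positive & labels)),
        tn=int(np.sum(~positive & ~labels)),
    )


def test_characteristics(
    t: ContingencyTable,
) -> tuple[float | None, float | None, float | None, float | None]:
    """(sensitivity, specificity, PPV, NPV); a quantity whose denominator
    is zero is returned as None rather than silently zero."""
    sens = t.tp / t.diseased if t.diseased > 0 else None
    spec = t.tn / t.non_diseased if t.non_diseased > 0 else None
    ppv = t.tp / (t.tp + t.fp) if (t.tp + t.fp) > 0 else None
    npv = t.tn / (t.tn + t.fn) if (t.tn + t.fn) > 0 else None
    return sens, spec, ppv, npv


def likelihood_ratios(sens: float, spec: float) -> tuple[float, float]:
    """LR+ = sens/(1-spec), LR- = (1-sens)/spec.

    A perfect specificity yields LR+ = +inf; zero specificity yields
    LR- = +inf.
    """
    lr_pos = math.inf if spec >= 1.0 else sens / (1.0 - spec)
    lr_neg = math.inf if spec <= 0.0 else (1.0 - sens) / spec
    return lr_pos, lr_neg


def prevalence_adjusted_lrs(
    sens: float, spec: float, prevalence: float
) -> tuple[float, float]:
    """Post-test odds of disease after a positive / negative result:
    the likelihood ratio times the pre-test odds ``p/(1-p)``."""
    if not 0.0 < prevalence < 1.0:
        raise ValueError(f"prevalence must be in (0, 1), got {prevalence}")
    odds = prevalence / (1.0 - prevalence)
    lr_pos, lr_neg = likelihood_ratios(sens, spec)
    return lr_pos * odds, lr_neg * odds


def proportion_ci(
    k: int, n: int, level: float = 0.95, method: str = "wilson"
) -> tuple[float, float]:
    """Binomial proportion CI: Wilson score (default) or Clopper-Pearson
    (``method="clopper-pearson"``). Always a subinterval of [0, 1]
    containing k/n."""
    if not 0 <= k <= n or n <= 0:
        raise ValueError(f"need 0 <= k <= n with n > 0, got k={k}, n={n}")
    sm_method = {"wilson": "wilson", "clopper-pearson": "beta"}.get(method)
    if sm_method is None:
        raise ValueError(f"method must be 'wilson' or 'clopper-pearson', got {method!r}")
    lo, hi = proportion_confint(k, n, alpha=1.0 - level, method=sm_method)
    # snap the exact boundary cases (k=0, k=n) against round-off
    lo = 0.0 if k == 0 else max(0.0, float(lo))
    hi = 1.0 if k == n else min(1.0, float(hi))
    return lo, hi


def lr_ci(
    t: ContingencyTable, which: str, level: float = 0.95
) -> tuple[float, float, bool]:
    """Log-method CI for a likelihood ratio.

    Returns (lo, hi, continuity_corrected). When a cell required by the
    variance formula is zero, 0.5 is added to every cell and the flag is
    set. A fully degenerate table (a whole margin empty) raises.
    """
    if which not in ("pos", "neg"):
        raise ValueError(f"which must be 'pos' or 'neg', got {which!r}")
    if t.diseased == 0 or t.non_diseased == 0:
        raise ValueError("degenerate table: an entire disease margin is empty")
    tp, fp, fn, tn = float(t.tp), float(t.fp), float(t.fn), float(t.tn)
    needs = (tp, fp) if which == "pos" else (fn, tn)
    corrected = any(c == 0 for c in needs)
    if corrected:
        tp, fp, fn, tn = tp + 0.5, fp + 0.5, fn + 0.5, tn + 0.5
    m, w = tp + fn, fp + tn
    if which == "pos":
        lr = (tp / m) / (fp / w)
        se = math.sqrt(1.0 / tp - 1.0 / m + 1.0 / fp - 1.0 / w)
    else:
        lr = (fn / m) / (tn / w)
        se = math.sqrt(1.0 / fn - 1.0 / m + 1.0 / tn - 1.0 / w)
    z = norm.ppf(0.5 + level / 2.0)
    return lr * math.exp(-z * se), lr * math.exp(z * se), corrected


def summarize_table(
    t: ContingencyTable,
    prevalence: float,
    threshold: int,
    stratum: str = "all",
    level: float = 0.95,
    ci_method: str = "wilson",
) -> DiagnosticSummary:
    """Full characteristics panel for one contingency table.

    ``prevalence`` drives the prevalence-adjusted likelihood ratios (the
    analysis uses the whole cohort's prevalence in every stratum);
    predictive values come from the table's own margins.
    """
    summary = DiagnosticSummary(
        stratum=stratum, threshold=threshold, table=t, prevalence=prevalence
    )
    sens, spec, ppv, npv = test_characteristics(t)
    summary.sensitivity, summary.specificity = sens, spec
    summary.ppv, summary.npv = ppv, npv
    if sens is not None:
        summary.sensitivity_ci = proportion_ci(t.tp, t.diseased, level, ci_method)
    else:
        summary.notes.append("sensitivity undefined: no diseased subjects")
    if spec is not None:
        summary.specificity_ci = proportion_ci(t.tn, t.non_diseased, level, ci_method)
    else:
        summary.notes.append("specificity undefined: no non-diseased subjects")
    if ppv is not None:
        summary.ppv_ci = proportion_ci(t.tp, t.tp + t.fp, level, ci_method)
    else:
        summary.notes.append("ppv undefined: no test-positive subjects")
    if npv is not None:
        summary.npv_ci = proportion_ci(t.tn, t.tn + t.fn, level, ci_method)
    else:
        summary.notes.append("npv undefined: no test-negative subjects")
    if sens is not None and spec is not None:
        odds = prevalence / (1.0 - prevalence)
        summary.lr_pos, summary.lr_neg = likelihood_ratios(sens, spec)
        summary.lr_pos_prev, summary.lr_neg_prev = prevalence_adjusted_lrs(
            sens, spec, prevalence
        )
        for which, attr in (("pos", "lr_pos"), ("neg", "lr_neg")):
            lo, hi, corrected = lr_ci(t, which, level)
            setattr(summary, f"{attr}_ci", (lo, hi))
            setattr(summary, f"{attr}_prev_ci", (lo * odds, hi * odds))
            if corrected:
                summary.notes.append(f"lr_{which}: +0.5 continuity correction applied")
    return summary


def summary_table(
    scores: Sequence[float],
    labels: Sequence[bool],
    ages: Sequence[float] | None = None,
    thresholds: Sequence[int] = (2, 3, 4),
    strata: Sequence[str] = ("all", "teen", "preteen"),
    prevalence: float | None = None,
    level: float = 0.95,
    ci_method: str = "wilson",
) -> list[DiagnosticSummary]:
    """One :class:`DiagnosticSummary` per (threshold, stratum).

    Age strata (teen >= 13 y / preteen < 13 y) need ``ages``. When
    ``prevalence`` is None the whole cohort's own prevalence is used for
    the adjusted likelihood ratios in every stratum.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if prevalence is None:
        prevalence = float(labels.mean())
    masks: dict[str, np.ndarray] = {}
    for stratum in strata:
        if stratum == "all":
            masks[stratum] = np.ones_like(labels, dtype=bool)
        elif stratum in ("teen", "preteen"):
            if ages is None:
                raise ValueError(f"ages required for stratum {stratum!r}")
            ages_arr = np.asarray(ages, dtype=float)
            masks[stratum] = ages_arr >= 13.0 if stratum == "teen" else ages_arr < 13.0
        else:
            raise ValueError(f"unknown stratum {stratum!r}")
    out: list[DiagnosticSummary] = []
    for threshold in thresholds:
        for stratum, mask in masks.items():
            t = build_contingency(scores[mask], labels[mask], threshold)
            out.append(
                summarize_table(t, prevalence, threshold, stratum, level, ci_method)
            )
    return out


def summaries_to_frame(summaries: Sequence[DiagnosticSummary]) -> pd.DataFrame:
    """Flatten summaries for CSV export."""
    rows = []
    for s in summaries:
        row = {
            "stratum": s.stratum,
            "threshold": s.threshold,
            "n": s.table.n,
            "tp": s.table.tp,
            "fp": s.table.fp,
            "fn": s.table.fn,
            "tn": s.table.tn,
            "prevalence": s.prevalence,
        }
        for name in ("sensitivity", "specificity", "ppv", "npv",
                     "lr_pos", "lr_neg", "lr_pos_prev", "lr_neg_prev"):
            row[name] = getattr(s, name)
            ci = getattr(s, f"{name}_ci")
            row[f"{name}_lo"] = None if ci is None else ci[0]
            row[f"{name}_hi"] = None if ci is None else ci[1]
        row["notes"] = "; ".join(s.notes)
        rows.append(row)
    return pd.DataFrame(rows)


def round_half_up(value: float, ndigits: int) -> float:
    """Decimal half-up rounding for report display (internal values are
    never rounded)."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))
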