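"""ROC curves and AUC estimation over the ordinal 0-8 score.

The empirical AUC is computed by tie-corrected pair counting (a
case-control pair contributes 1 when the case scores higher, 0.5 on a
tie), implemented through midranks; this equals the trapezoidal area
under the empirical ROC exactly. Variances, confidence intervals and
curve comparisons use the DeLong nonparametric method: each subject
contributes a placement value (the fraction of the other class it beats,
ties counted half), and the AUC variance combines the per-class sample
variances of those placements. Paired comparisons (two scores on the
same subjects, e.g. parent- vs child-reported) additionally use the
covariance of placement differences; unpaired comparisons (disjoint
strata) use a plain two-sample z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

__all__ = [
    "RocCurve",
    "AucEstimate",
    "roc_points",
    "auc",
    "trapezoid_auc",
    "auc_ci_delong",
    "compare_auc_unpaired",
    "compare_auc_paired",
]


@dataclass(frozen=True)
class RocCurve:
    """Operating points from the (0,0) anchor to the (1,1) anchor.

    ``thresholds[i]`` is the score cut (predict positive when
    score >= threshold) giving (fpr[i], tpr[i]); the anchors carry
    +inf and -inf cuts.
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray


@dataclass(frozen=True)
class AucEstimate:
    """Empirical AUC with DeLong variance and normal-approximation CI."""

    auc: float
    variance: float
    ci: tuple[float, float]
    n_pos: int
    n_neg: int
    level: float = 0.95
    ci_truncated: bool = False


def _validate(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-d sequences")
    if labels.all() or not labels.any():
        raise ValueError("need at least one positive and one negative label")
    return scores, labels


def roc_points(scores, labels) -> RocCurve:
    """Empirical ROC: one operating point per distinct score, plus anchors."""
    scores, labels = _validate(scores, labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    cuts = np.unique(scores)[::-1]  # descending: strictest cut first
    thresholds = [math.inf]
    fpr = [0.0]
    tpr = [0.0]
    for cut in cuts:
        predicted = scores >= cut
        tpr.append(float(np.sum(predicted & labels)) / n_pos)
        fpr.append(float(np.sum(predicted & ~labels)) / n_neg)
        thresholds.append(float(cut))
    if fpr[-1] != 1.0 or tpr[-1] != 1.0:
        thresholds.append(-math.inf)
        fpr.append(1.0)
        tpr.append(1.0)
    return RocCurve(
        thresholds=np.asarray(thresholds),
        fpr=np.asarray(fpr),
        tpr=np.asarray(tpr),
    )


def trapezoid_auc(curve: RocCurve) -> float:
    """Trapezoidal area under an ROC curve."""
    return float(np.trapezoid(curve.tpr, curve.fpr))


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values (midrank convention).

    For a positive subject: the fraction of negatives it outscores (ties
    half). For a negative subject: the fraction of positives scoring
    above it (ties half). Both vectors have mean equal to the AUC.
    """
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks_all = rankdata(scores)  # midranks
    ranks_pos = rankdata(scores[labels])
    ranks_neg = rankdata(scores[~labels])
    v_pos = (ranks_all[labels] - ranks_pos) / n_neg
    v_neg = 1.0 - (ranks_all[~labels] - ranks_neg) / n_pos
    return v_pos, v_neg


def auc(scores, labels) -> float:
    """Tie-corrected pair-counting AUC (probability a random case
    outscores a random control, ties worth half)."""
    scores, labels = _validate(scores, labels)
    v_pos, _ = _placements(scores, labels)
    return float(v_pos.mean())


def auc_ci_delong(scores, labels, level: float = 0.95) -> AucEstimate:
    """AUC with DeLong variance and a normal CI truncated to [0, 1]."""
    scores, labels = _validate(scores, labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos < 2 or n_neg < 2:
        raise ValueError(f"need >= 2 of each class, got n_pos={n_pos}, n_neg={n_neg}")
    v_pos, v_neg = _placements(scores, labels)
    estimate = float(v_pos.mean())
    variance = float(np.var(v_pos, ddof=1) / n_pos + np.var(v_neg, ddof=1) / n_neg)
    z = float(norm.ppf(0.5 + level / 2.0))
    half = z * math.sqrt(variance)
    lo, hi = estimate - half, estimate + half
    truncated = bool(lo < 0.0 or hi > 1.0)
    return AucEstimate(
        auc=estimate,
        variance=variance,
        ci=(max(lo, 0.0), min(hi, 1.0)),
        n_pos=n_pos,
        n_neg=n_neg,
        level=level,
        ci_truncated=truncated,
    )


def compare_auc_unpaired(a: AucEstimate, b: AucEstimate) -> tuple[float, float]:
    """Two-sample z-test for AUCs estimated on disjoint subject sets."""
    var = a.variance + b.variance
    if var <= 0.0:
        if a.auc == b.auc:
            return 0.0, 1.0
        raise ValueError("zero combined variance with unequal AUCs")
    z = (a.auc - b.auc) / math.sqrt(var)
    p = 2.0 * norm.sf(abs(z))
    return float(z), float(p)


def compare_auc_paired(scores_1, scores_2, labels) -> tuple[float, float]:
    """Paired DeLong test for two score vectors on the same subjects.

    The variance of the AUC difference subtracts twice the covariance of
    the placement values, which is what makes the paired test more
    powerful when the scores agree.
    """
    scores_1, labels_1 = _validate(scores_1, labels)
    scores_2, labels_2 = _validate(scores_2, labels)
    if scores_1.shape != scores_2.shape:
        raise ValueError("paired score vectors must have equal length")
    n_pos = int(labels_1.sum())
    n_neg = labels_1.size - n_pos
    if n_pos < 2 or n_neg < 2:
        raise ValueError(f"need >= 2 of each class, got n_pos={n_pos}, n_neg={n_neg}")
    v1_pos, v1_neg = _placements(scores_1, labels_1)
    v2_pos, v2_neg = _placements(scores_2, labels_2)
    auc_1, auc_2 = float(v1_pos.mean()), float(v2_pos.mean())
    s_pos = np.cov(v1_pos, v2_pos, ddof=1)
    s_neg = np.cov(v1_neg, v2_neg, ddof=1)
    var = (
        (s_pos[0, 0] + s_pos[1, 1] - 2.0 * s_pos[0, 1]) / n_pos
        + (s_neg[0, 0] + s_neg[1, 1] - 2.0 * s_neg[0, 1]) / n_neg
    )
    if var <= 0.0:
        if auc_1 == auc_2:
            return 0.0, 1.0
        raise ValueError("zero paired variance with unequal AUCs")
    z = (auc_1 - auc_2) / math.sqrt(var)
    p = 2.0 * norm.sf(abs(z))
    return float(z), float(p)
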