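"""Auxiliary nonparametric tests and descriptive summaries.

Ordinal 0-8 questionnaire scores are far from normal, so paired
comparisons (parent vs child report of the same child) use the Wilcoxon
signed-rank test, unpaired group comparisons use the Mann-Whitney U
test, normality itself is checked with a one-sample Kolmogorov-Smirnov
test, and descriptives are medians with 25th/75th quartiles.

Exact small-sample behaviour:

* Wilcoxon: zero differences are dropped (Wilcoxon's rule, not Pratt's);
  absolute differences are midranked. With at most 12 nonzero
  differences the two-sided p-value is computed by exhaustive
  enumeration of all 2^n sign patterns (valid with ties); otherwise a
  tie-corrected, continuity-corrected normal approximation is used.
* Mann-Whitney: exact null distribution when there are no ties and
  n_A * n_B <= 400, else the tie-corrected normal approximation with
  continuity correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import kstest, mannwhitneyu, norm, rankdata

__all__ = [
    "TestResult",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "ks_normality",
    "median_iqr",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float | None
    p_value: float
    n_effective: int
    method_notes: str


def _wilcoxon_exact_two_sided(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided p by full enumeration of sign patterns on the observed
    (possibly tied) ranks: min(1, 2 * min tail)."""
    n = ranks.size
    totals = np.zeros(1)
    for r in ranks:  # distribution of W+ over all 2^n sign assignments
        totals = np.concatenate([totals, totals + r])
    lower = np.mean(totals <= w_plus + 1e-9)
    upper = np.mean(totals >= w_plus - 1e-9)
    return min(1.0, 2.0 * min(lower, upper))


def wilcoxon_signed_rank(differences, exact_max: int = 12) -> TestResult:
    """Paired-sample Wilcoxon signed-rank test on precomputed differences.

    Returns the W+ statistic (sum of ranks of positive differences).
    All-zero differences yield a flagged degenerate result with p = 1.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return TestResult(
            statistic=None, p_value=1.0, n_effective=0,
            method_notes="degenerate: all differences zero (zeros dropped)",
        )
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    has_ties = np.unique(np.abs(d)).size < n
    if n <= exact_max:
        p = _wilcoxon_exact_two_sided(ranks, w_plus)
        notes = "exact enumeration of sign patterns; zeros dropped"
        if has_ties:
            notes += "; midranks for tied |differences|"
        return TestResult(statistic=w_plus, p_value=p, n_effective=n, method_notes=notes)
    mean = n * (n + 1) / 4.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0.0:
        return TestResult(
            statistic=w_plus, p_value=1.0, n_effective=n,
            method_notes="degenerate: zero variance after tie correction",
        )
    delta = w_plus - mean
    z = (delta - 0.5 * np.sign(delta)) / math.sqrt(var)  # continuity toward mean
    p = min(1.0, 2.0 * norm.sf(abs(z)))
    notes = "normal approximation with tie and continuity corrections; zeros dropped"
    return TestResult(statistic=w_plus, p_value=p, n_effective=n, method_notes=notes)


def mann_whitney_u(x, y, exact_max_product: int = 400) -> TestResult:
    """Two-sided Mann-Whitney U test; the statistic is U for the first
    group (midranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    exact = (not has_ties) and (x.size * y.size <= exact_max_product)
    method = "exact" if exact else "asymptotic"
    res = mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=not exact
    )
    notes = (
        "exact null distribution (no ties)"
        if exact
        else "normal approximation with tie and continuity corrections"
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_effective=int(x.size + y.size),
        method_notes=notes,
    )


def ks_normality(x, lilliefors: bool = False) -> TestResult:
    """One-sample Kolmogorov-Smirnov check against a normal with the
    sample's own mean and SD.

    With estimated parameters the asymptotic p-value is anti-conservative
    (the Lilliefors caveat, recorded in the notes); pass
    ``lilliefors=True`` for the corrected variant.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 5:
        raise ValueError(f"need n >= 5, got {x.size}")
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        raise ValueError("zero variance sample")
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as sm_lilliefors

        stat, p = sm_lilliefors(x, dist="norm")
        notes = "Lilliefors-corrected KS (parameters estimated)"
    else:
        stat, p = kstest(x, "norm", args=(float(x.mean()), sd))
        notes = (
            "one-sample KS against N(sample mean, sample SD); parameters "
            "estimated from the data, so the asymptotic p-value is "
            "anti-conservative (Lilliefors caveat)"
        )
    return TestResult(
        statistic=float(stat), p_value=float(p), n_effective=int(x.size), method_notes=notes
    )


def median_iqr(x) -> tuple[float, float, float]:
    """(median, 25th, 75th quartile) by linear interpolation between
    order statistics."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    q50, q25, q75 = np.percentile(x, [50, 25, 75], method="linear")
    return float(q50), float(q25), float(q75)
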