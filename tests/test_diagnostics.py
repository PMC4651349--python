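"""Diagnostic metrics: contingency tables, the accuracy-panel characteristics,
likelihood ratios (plain and prevalence-adjusted) and their intervals."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import norm

from stopbang.diagnostics import (
    ContingencyTable,
    build_contingency,
    likelihood_ratios,
    lr_ci,
    prevalence_adjusted_lrs,
    proportion_ci,
    round_half_up,
    summary_table,
)
from stopbang.diagnostics import test_characteristics as characteristics


def wilson_quadratic(k, n, level=0.95):
    """Direct solution of the Wilson score quadratic, as an oracle."""
    z = norm.ppf(0.5 + level / 2)
    p = k / n
    center = (p + z**2 / (2 * n)) / (1 + z**2 / n)
    half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / (1 + z**2 / n)
    return center - half, center + half


class TestBuildContingency:
    def test_enumeration(self):
        t = build_contingency([3, 2, 3, 0], [True, True, False, False], threshold=3)
        assert (t.tp, t.fn, t.fp, t.tn) == (1, 1, 1, 1)

    def test_degenerate_cuts(self):
        scores, labels = [0, 3, 5, 8], [True, False, True, False]
        low = build_contingency(scores, labels, threshold=0)
        assert low.fn == low.tn == 0
        high = build_contingency(scores, labels, threshold=9)
        assert high.tp == high.fp == 0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_contingency([], [], 3)


class TestCharacteristics:
    def test_teens_row_counts(self):
        # counts consistent with the teens stratum at score >= 3
        t = ContingencyTable(tp=9, fn=5, fp=29, tn=133)
        sens, spec, ppv, npv = characteristics(t)
        assert round_half_up(sens, 2) == 0.64
        assert round_half_up(spec, 2) == 0.82
        assert round_half_up(ppv, 2) == 0.24
        assert round_half_up(npv, 2) == 0.96

    def test_perfect_classifier(self):
        t = ContingencyTable(tp=10, fn=0, fp=0, tn=20)
        assert characteristics(t) == (1.0, 1.0, 1.0, 1.0)

    def test_zero_tp_gives_zero_ppv(self):
        t = ContingencyTable(tp=0, fn=3, fp=4, tn=5)
        assert characteristics(t)[2] == 0.0

    def test_zero_denominator_is_none_not_zero(self):
        t = ContingencyTable(tp=0, fn=0, fp=4, tn=5)
        sens, spec, ppv, npv = characteristics(t)
        assert sens is None and spec is not None

    @given(
        tp=st.integers(0, 50), fn=st.integers(0, 50),
        fp=st.integers(0, 50), tn=st.integers(0, 50),
    )
    def test_count_conservation(self, tp, fn, fp, tn):
        t = ContingencyTable(tp=tp, fn=fn, fp=fp, tn=tn)
        sens, spec, _, _ = characteristics(t)
        if sens is not None:
            assert sens * t.diseased == pytest.approx(tp)
        if spec is not None:
            assert spec * t.non_diseased == pytest.approx(tn)


class TestLikelihoodRatios:
    def test_teens_row(self):
        sens, spec = 9 / 14, 133 / 162
        lr_pos, lr_neg = likelihood_ratios(sens, spec)
        assert round_half_up(lr_pos, 1) == 3.6
        assert round_half_up(lr_neg, 1) == 0.4

    def test_perfect_test(self):
        lr_pos, lr_neg = likelihood_ratios(1.0, 1.0)
        assert math.isinf(lr_pos) and lr_neg == 0.0

    def test_uninformative_test(self):
        assert likelihood_ratios(0.5, 0.5) == (1.0, 1.0)


class TestPrevalenceAdjustedLrs:
    def test_all_row(self):
        lr_pos_prev, lr_neg_prev = prevalence_adjusted_lrs(0.56, 0.84, 25 / 312)
        assert round_half_up(lr_pos_prev, 1) == 0.3
        assert round_half_up(lr_neg_prev, 2) == 0.05

    def test_teens_row(self):
        _, lr_neg_prev = prevalence_adjusted_lrs(9 / 14, 133 / 162, 25 / 312)
        assert round_half_up(lr_neg_prev, 2) == 0.04

    def test_even_prevalence_reduces_to_plain_lr(self):
        lr_pos, lr_neg = likelihood_ratios(0.7, 0.8)
        adj_pos, adj_neg = prevalence_adjusted_lrs(0.7, 0.8, 0.5)
        assert adj_pos == pytest.approx(lr_pos)
        assert adj_neg == pytest.approx(lr_neg)

    @given(
        sens=st.floats(0.05, 0.99), spec=st.floats(0.05, 0.99),
        prev=st.floats(0.01, 0.99),
    )
    def test_post_test_odds_identities(self, sens, spec, prev):
        """LR+[P] = PPV/(1-PPV) and LR-[P] = (1-NPV)/NPV when the
        predictive values are computed at the same prevalence via Bayes."""
        ppv = sens * prev / (sens * prev + (1 - spec) * (1 - prev))
        npv = spec * (1 - prev) / (spec * (1 - prev) + (1 - sens) * prev)
        adj_pos, adj_neg = prevalence_adjusted_lrs(sens, spec, prev)
        assert abs(adj_pos - ppv / (1 - ppv)) < 1e-12 * max(1, adj_pos)
        assert abs(adj_neg - (1 - npv) / npv) < 1e-12 * max(1, adj_neg)


class TestProportionCi:
    def test_boundaries(self):
        assert proportion_ci(0, 10)[0] == 0.0
        assert proportion_ci(10, 10)[1] == 1.0

    @pytest.mark.parametrize("k,n", [(9, 14), (1, 30), (25, 312), (133, 162)])
    def test_wilson_matches_quadratic_oracle(self, k, n):
        lo, hi = proportion_ci(k, n, method="wilson")
        olo, ohi = wilson_quadratic(k, n)
        assert lo == pytest.approx(olo, abs=1e-10)
        assert hi == pytest.approx(ohi, abs=1e-10)

    def test_contains_point_estimate(self):
        for method in ("wilson", "clopper-pearson"):
            lo, hi = proportion_ci(9, 14, method=method)
            assert lo <= 9 / 14 <= hi
            assert 0.0 <= lo <= hi <= 1.0


class TestLrCi:
    def test_interval_straddles_estimate(self):
        t = ContingencyTable(tp=40, fn=20, fp=30, tn=110)
        sens, spec, _, _ = characteristics(t)
        lr_pos, _ = likelihood_ratios(sens, spec)
        lo, hi, corrected = lr_ci(t, "pos")
        assert lo < lr_pos < hi and not corrected

    def test_quadrupling_counts_roughly_halves_log_width(self):
        t1 = ContingencyTable(tp=10, fn=10, fp=10, tn=10)
        t4 = ContingencyTable(tp=40, fn=40, fp=40, tn=40)
        width = lambda t: math.log(lr_ci(t, "pos")[1]) - math.log(lr_ci(t, "pos")[0])
        assert width(t4) == pytest.approx(width(t1) / 2, rel=0.01)

    def test_zero_cell_triggers_continuity_flag(self):
        t = ContingencyTable(tp=5, fn=5, fp=0, tn=10)
        lo, hi, corrected = lr_ci(t, "pos")
        assert corrected and 0 < lo < hi < math.inf

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValueError):
            lr_ci(ContingencyTable(tp=0, fn=0, fp=5, tn=5), "pos")


class TestSummaryTable:
    @pytest.fixture()
    def cohort(self, rng):
        n = 312
        labels = rng.random(n) < 0.08
        scores = np.where(labels, rng.binomial(8, 0.38, n), rng.binomial(8, 0.19, n))
        ages = rng.uniform(9, 17.6, n)
        return scores, labels, ages

    def test_cardinality(self, cohort):
        scores, labels, ages = cohort
        rows = summary_table(scores, labels, ages=ages)
        assert len(rows) == 9
        assert {(r.threshold, r.stratum) for r in rows} == {
            (t, s) for t in (2, 3, 4) for s in ("all", "teen", "preteen")
        }

    def test_threshold_monotonicity_full_sweep(self, cohort):
        scores, labels, _ = cohort
        rows = summary_table(
            scores, labels, thresholds=range(0, 10), strata=("all",)
        )
        sens = [r.sensitivity for r in rows]
        spec = [r.specificity for r in rows]
        assert all(a >= b for a, b in zip(sens, sens[1:]))
        assert all(a <= b for a, b in zip(spec, spec[1:]))

    def test_stratum_prevalence_is_cohort_wide(self, cohort):
        scores, labels, ages = cohort
        rows = summary_table(scores, labels, ages=ages)
        assert len({r.prevalence for r in rows}) == 1
        assert rows[0].prevalence == pytest.approx(labels.mean())

    def test_stratum_without_disease_is_flagged_not_crashed(self):
        scores = np.array([1, 2, 3, 4])
        labels = np.array([False, False, False, False])
        ages = np.array([14.0, 15.0, 10.0, 11.0])
        rows = summary_table(scores, labels, ages=ages, thresholds=(3,), prevalence=0.08)
        for row in rows:
            assert row.sensitivity is None
            assert any("sensitivity undefined" in note for note in row.notes)

    def test_wilson_coverage_of_generating_parameters(self, rng):
        """Estimated sens/spec at threshold 3 land inside their own
        Wilson CIs (vs the generating values) in >= 93% of simulations."""
        p_osa, p_healthy = 0.38, 0.19
        from scipy.stats import binom

        true_sens = binom.sf(2, 8, p_osa)
        true_spec = 1 - binom.sf(2, 8, p_healthy)
        hits_sens = hits_spec = runs = 0
        for _ in range(200):
            labels = rng.random(312) < 0.08
            if labels.sum() < 2:
                continue
            scores = np.where(
                labels, rng.binomial(8, p_osa, 312), rng.binomial(8, p_healthy, 312)
            )
            row = summary_table(scores, labels, thresholds=(3,), strata=("all",))[0]
            runs += 1
            hits_sens += row.sensitivity_ci[0] <= true_sens <= row.sensitivity_ci[1]
            hits_spec += row.specificity_ci[0] <= true_spec <= row.specificity_ci[1]
        assert hits_sens / runs >= 0.93
        assert hits_spec / runs >= 0.93


class TestRounding:
    @pytest.mark.parametrize(
        "value,ndigits,expected",
        [(0.235, 2, 0.24), (0.05, 1, 0.1), (3.591, 1, 3.6), (0.0449, 2, 0.04)],
    )
    def test_half_up(self, value, ndigits, expected):
        assert round_half_up(value, ndigits) == expected
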