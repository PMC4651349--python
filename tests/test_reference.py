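"""Pediatric references: LMS z-scores and percentiles, blood-pressure
regression percentiles, neck lookup, anthropometric flags."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import norm

from stopbang.reference import (
    ReferenceRangeError,
    anthropometric_flags,
    bmi_percentile,
    bp_percentile,
    compute_bmi,
    expected_bp,
    interpolate_lms,
    lms_inverse,
    lms_zscore,
    load_reference_set,
    neck_p95,
)
from tests.conftest import make_record


class TestBmi:
    @pytest.mark.parametrize(
        "weight,height,expected",
        [(60.0, 170.0, 20.76), (50.0, 100.0, 50.0)],
    )
    def test_arithmetic(self, weight, height, expected):
        assert compute_bmi(weight, height) == pytest.approx(expected, abs=0.005)

    def test_linear_in_weight(self):
        assert compute_bmi(80, 160) == pytest.approx(2 * compute_bmi(40, 160))

    @pytest.mark.parametrize("weight,height", [(0, 160), (-1, 160), (50, 0)])
    def test_nonpositive_rejected(self, weight, height):
        with pytest.raises(ValueError):
            compute_bmi(weight, height)


class TestLmsZscore:
    def test_median_maps_to_z_zero(self):
        assert lms_zscore(20.0, -1.5, 20.0, 0.1) == pytest.approx(0.0)

    def test_closed_form_example(self):
        # L=1 reduces to (x - M)/(M S): (22-20)/2 = 1 -> 84.13th pct
        z = lms_zscore(22.0, 1.0, 20.0, 0.1)
        assert z == pytest.approx(1.0)
        assert norm.cdf(z) * 100 == pytest.approx(84.13, abs=0.01)

    def test_l_to_zero_continuity(self):
        for x in np.linspace(15.0, 30.0, 25):
            limit = np.log(x / 20.0) / 0.1
            assert abs(lms_zscore(x, 1e-8, 20.0, 0.1) - limit) < 1e-6

    @given(
        z=st.floats(-3.5, 3.5),
        L=st.floats(-3.0, 3.0),
        M=st.floats(10.0, 40.0),
        S=st.floats(0.02, 0.2),
    )
    def test_inverse_round_trip(self, z, L, M, S):
        x = lms_inverse(z, L, M, S)
        if x <= 0 or not np.isfinite(x):  # outside the Box-Cox support
            return
        assert lms_zscore(x, L, M, S) == pytest.approx(z, abs=1e-9, rel=1e-9)


@pytest.fixture()
def two_row_lms():
    return pd.DataFrame(
        [
            {"sex": "male", "age_months": 120, "L": 1.0, "M": 18.0, "S": 0.1},
            {"sex": "male", "age_months": 132, "L": 1.0, "M": 20.0, "S": 0.1},
        ]
    )


class TestBmiPercentile:
    def test_median_at_tabulated_age_is_50th(self, two_row_lms):
        assert bmi_percentile(18.0, "male", 120, two_row_lms) == pytest.approx(50.0)

    def test_midpoint_interpolation(self, two_row_lms):
        # halfway between the knots the interpolated median is 19
        assert bmi_percentile(19.0, "male", 126, two_row_lms) == pytest.approx(50.0)

    def test_strictly_increasing_in_bmi(self, two_row_lms):
        grid = [bmi_percentile(b, "male", 126, two_row_lms) for b in np.linspace(14, 26, 30)]
        assert all(a < b for a, b in zip(grid, grid[1:]))

    def test_age_outside_range_names_range(self, two_row_lms):
        with pytest.raises(ReferenceRangeError, match=r"\[120, 132\]"):
            bmi_percentile(18.0, "male", 200, two_row_lms)

    def test_continuity_across_knots(self, refs):
        # fixed measurement: percentile as a function of age has no jumps
        # at tabulated knots
        table = refs.bmi_lms
        knots = table.loc[table.sex == "male", "age_months"].to_numpy()[1:-1]
        for knot in knots:
            below = bmi_percentile(20.0, "male", knot - 1e-7, table)
            above = bmi_percentile(20.0, "male", knot + 1e-7, table)
            assert abs(below - above) < 1e-6


class TestBpPercentile:
    def test_observed_equals_expected_is_50th(self, toy_refs):
        pct = bp_percentile(
            100.0, "male", "systolic", 12.0, 150.0,
            toy_refs.height_lms, toy_refs.bp_coefficients,
        )
        assert pct == pytest.approx(50.0)

    def test_observed_at_95th_quantile(self, toy_refs):
        pct = bp_percentile(
            100.0 + 1.645 * 10.0, "male", "systolic", 12.0, 150.0,
            toy_refs.height_lms, toy_refs.bp_coefficients,
        )
        assert pct == pytest.approx(95.0, abs=0.1)

    def test_flat_model_is_plain_normal_cdf(self, toy_refs):
        pct = bp_percentile(
            110.0, "male", "systolic", 12.0, 150.0,
            toy_refs.height_lms, toy_refs.bp_coefficients,
        )
        assert pct == pytest.approx(84.13, abs=0.01)

    def test_polynomial_terms_enter(self, refs):
        flat, _sd = expected_bp("male", "systolic", 10.0, 0.0, refs.bp_coefficients)
        older, _sd = expected_bp("male", "systolic", 15.0, 0.0, refs.bp_coefficients)
        taller, _sd = expected_bp("male", "systolic", 10.0, 1.5, refs.bp_coefficients)
        assert older > flat  # pressure rises with age
        assert taller > flat  # and with relative height


class TestNeckLookup:
    def test_nearest_integer_age(self, refs):
        assert neck_p95("male", 12.4, refs.neck_p95) == neck_p95("male", 12.0, refs.neck_p95)
        assert neck_p95("male", 12.6, refs.neck_p95) == neck_p95("male", 13.0, refs.neck_p95)

    def test_out_of_range_names_coverage(self, refs):
        with pytest.raises(ReferenceRangeError, match="covered ages"):
            neck_p95("male", 30.0, refs.neck_p95)


class TestAnthropometricFlags:
    def test_bp_flag_uses_max_rule(self, toy_refs, record_factory):
        rec = record_factory("a", systolic_bp=100.0 + 1.8 * 10.0, diastolic_bp=58.0)
        flags = anthropometric_flags(rec, toy_refs)
        assert flags.systolic_percentile > 95.0 > flags.diastolic_percentile
        assert flags.bp_flag

    def test_bp_flag_boundary_is_inclusive(self, toy_refs, record_factory):
        exactly_95 = 100.0 + norm.ppf(0.95) * 10.0
        rec = record_factory("a", systolic_bp=exactly_95)
        assert anthropometric_flags(rec, toy_refs).bp_flag

    def test_bmi_flag_is_strict(self, toy_refs, record_factory):
        # toy LMS: L=1, M=18, S=0.1 -> bmi at exactly the 95th percentile
        bmi_95 = 18.0 * (1.0 + 0.1 * norm.ppf(0.95))
        rec = record_factory("a", weight=bmi_95 * 1.5**2, height=150.0)
        flags = anthropometric_flags(rec, toy_refs)
        assert flags.bmi_percentile == pytest.approx(95.0, abs=1e-6)
        assert not flags.bmi_flag
        heavier = record_factory("b", weight=(bmi_95 + 0.05) * 1.5**2, height=150.0)
        assert anthropometric_flags(heavier, toy_refs).bmi_flag

    def test_neck_flag_boundary(self, toy_refs, record_factory):
        above = record_factory("a", neck_circumference=35.1)
        below = record_factory("b", neck_circumference=34.9)
        assert anthropometric_flags(above, toy_refs).neck_flag
        assert not anthropometric_flags(below, toy_refs).neck_flag

    def test_configurable_bmi_cut(self, toy_refs, record_factory):
        bmi_93 = 18.0 * (1.0 + 0.1 * norm.ppf(0.93))
        rec = record_factory("a", weight=bmi_93 * 1.5**2, height=150.0)
        assert anthropometric_flags(rec, toy_refs, bmi_cut=90.0).bmi_flag
        assert not anthropometric_flags(rec, toy_refs, bmi_cut=95.0).bmi_flag

    def test_incomplete_record_rejected(self, toy_refs, record_factory):
        rec = record_factory("a", weight=None)
        with pytest.raises(ValueError, match="weight"):
            anthropometric_flags(rec, toy_refs)

    def test_percentiles_strictly_inside_0_100(self, refs, record_factory):
        extreme = record_factory("a", weight=150.0, height=140.0, systolic_bp=250.0)
        flags = anthropometric_flags(extreme, refs)
        for pct in (flags.bmi_percentile, flags.systolic_percentile, flags.bp_percentile_max):
            assert 0.0 < pct < 100.0


class TestBundledTables:
    def test_schema_and_coverage(self, refs):
        assert set(refs.bmi_lms.columns) == {"sex", "age_months", "L", "M", "S"}
        for table in (refs.bmi_lms, refs.height_lms):
            for sex in ("male", "female"):
                ages = table.loc[table.sex == sex, "age_months"].to_numpy()
                assert (np.diff(ages) > 0).all()
                assert ages.min() <= 9 * 12 and ages.max() >= 17.6 * 12
                assert (table.loc[table.sex == sex, "M"] > 0).all()
                assert (table.loc[table.sex == sex, "S"] > 0).all()
        assert set(refs.neck_p95.sex) == {"male", "female"}
        assert (refs.bp_coefficients.sd > 0).all()

    def test_default_set_loads_from_package(self):
        refs = load_reference_set()
        L, M, S = interpolate_lms(refs.bmi_lms, "female", 150.0)
        assert M > 0 and S > 0
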