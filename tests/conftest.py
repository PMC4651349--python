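import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def refs():
    """Bundled synthetic reference set."""
    from stopbang.reference import load_reference_set

    return load_reference_set()


@pytest.fixture()
def toy_refs():
    """Tiny hand-constructed reference set with easily checkable numbers:
    LMS tables with L=1 (plain normal), flat blood-pressure model
    (expected 100/60, SD 10), neck 95th percentile 35 cm at every age."""
    from stopbang.reference import ReferenceSet

    def lms(m_young: float, m_old: float, s: float) -> pd.DataFrame:
        rows = []
        for sex in ("male", "female"):
            rows.append({"sex": sex, "age_months": 60, "L": 1.0, "M": m_young, "S": s})
            rows.append({"sex": sex, "age_months": 300, "L": 1.0, "M": m_old, "S": s})
        return pd.DataFrame(rows)

    bp_rows = []
    for sex in ("male", "female"):
        for measure, intercept in (("systolic", 100.0), ("diastolic", 60.0)):
            row = {"sex": sex, "measure": measure, "intercept": intercept, "sd": 10.0}
            row.update({f"a{j}": 0.0 for j in range(1, 5)})
            row.update({f"h{j}": 0.0 for j in range(1, 5)})
            bp_rows.append(row)
    neck_rows = [
        {"sex": sex, "age_years": age, "p95_cm": 35.0}
        for sex in ("male", "female")
        for age in range(5, 26)
    ]
    return ReferenceSet(
        bmi_lms=lms(18.0, 18.0, 0.1),
        height_lms=lms(150.0, 150.0, 0.05),
        bp_coefficients=pd.DataFrame(bp_rows),
        neck_p95=pd.DataFrame(neck_rows),
    )


def make_record(
    subject_id="s1",
    age=14.0,
    sex="male",
    responses=None,
    **overrides,
):
    """A complete, unremarkable subject; questionnaire defaults to all
    'never' for both reporters."""
    from stopbang.cohort import QUESTIONNAIRE_ITEMS, REPORTERS, ResponseLevel, SubjectRecord

    full = {
        rep: {item: ResponseLevel.NEVER for item in QUESTIONNAIRE_ITEMS}
        for rep in REPORTERS
    }
    for rep, items in (responses or {}).items():
        full[rep].update(items)
    kwargs = dict(
        subject_id=subject_id,
        age=age,
        sex=sex,
        ethnicity="caucasian",
        height=150.0,
        weight=40.0,
        systolic_bp=100.0,
        diastolic_bp=60.0,
        neck_circumference=30.0,
        smr=3,
        ahi=0.3,
        responses=full,
    )
    kwargs.update(overrides)
    return SubjectRecord(**kwargs)


@pytest.fixture()
def record_factory():
    return make_record


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
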