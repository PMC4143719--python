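import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from haploblock.phenotype import (
    ExamRecord,
    NoUsableExamError,
    build_covariates,
    default_age_knots,
    derive_hypertension,
    derive_smoker_ever,
    dichotomize_age,
    rcs_basis,
)


def exams(sbp, dbp, meds=None, smokes=None):
    meds = meds or [False] * len(sbp)
    smokes = smokes or [None] * len(sbp)
    return [
        ExamRecord("x", k + 1, s, d, m, sm)
        for k, (s, d, m, sm) in enumerate(zip(sbp, dbp, meds, smokes))
    ]


class TestHypertension:
    @pytest.mark.parametrize(
        "sbp, dbp, meds, rule, expected",
        [
            # one exam exceeds both strict thresholds
            ([135, 150, 138, 141], [85, 95, 88, 92], None, "and", 1),
            # medication at any exam qualifies regardless of BP
            ([120] * 4, [70] * 4, [False, False, True, False], "and", 1),
            # boundary values do not qualify (strict inequalities)
            ([140] * 4, [90] * 4, None, "and", 0),
            # "or" rule: high systolic alone is enough
            ([150] * 4, [70] * 4, None, "or", 1),
            ([150] * 4, [70] * 4, None, "and", 0),
        ],
    )
    def test_rule(self, sbp, dbp, meds, rule, expected):
        assert derive_hypertension(exams(sbp, dbp, meds), rule=rule) == expected

    def test_missing_fields_never_qualify(self):
        recs = exams([None, 150], [95, None])
        assert derive_hypertension(recs, rule="and") == 0

    def test_all_missing_raises(self):
        recs = [ExamRecord("x", 1), ExamRecord("x", 2)]
        with pytest.raises(NoUsableExamError):
            derive_hypertension(recs)

    @given(
        st.lists(
            st.tuples(
                st.one_of(st.none(), st.floats(80, 220)),
                st.one_of(st.none(), st.floats(40, 130)),
                st.one_of(st.none(), st.booleans()),
            ),
            min_size=1,
            max_size=4,
        ),
        st.tuples(
            st.floats(80, 220), st.floats(40, 130), st.booleans()
        ),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_and_rule_order(self, fields, extra):
        """Adding an exam can only flip 0 -> 1; 'or' dominates 'and'."""
        recs = [
            ExamRecord("x", k + 1, s, d, m) for k, (s, d, m) in enumerate(fields)
        ]
        if not any(s is not None or d is not None or m is not None for s, d, m in fields):
            return
        y_and = derive_hypertension(recs, rule="and")
        y_or = derive_hypertension(recs, rule="or")
        assert y_or >= y_and
        more = recs + [ExamRecord("x", len(recs) + 1, *extra)]
        assert derive_hypertension(more, rule="and") >= y_and
        assert derive_hypertension(more, rule="or") >= y_or


@pytest.mark.parametrize(
    "smokes, expected",
    [
        ([False, False, True, False], 1),
        ([False, False, False, False], 0),
        ([None, False, None, False], 0),  # missing is not "yes"
        ([None, None, None, None], None),
    ],
)
def test_smoker_ever(smokes, expected):
    recs = exams([120] * 4, [70] * 4, smokes=smokes)
    assert derive_smoker_ever(recs) == expected


@pytest.mark.parametrize("age, expected", [(55, 1), (54.9, 0), (20, 0), (80, 1)])
def test_dichotomize_age(age, expected):
    assert dichotomize_age(age) == expected


def test_negative_age_raises():
    with pytest.raises(ValueError):
        dichotomize_age(-1)


class TestRcsBasis:
    def test_column_count_is_k_minus_1(self):
        x = np.linspace(0, 10, 50)
        assert rcs_basis(x, [2, 5, 8]).shape == (50, 2)
        assert rcs_basis(x, [1, 3, 5, 7, 9]).shape == (50, 4)

    def test_linear_data_gives_zero_nonlinear_coefficients(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 10, 200)
        y = 2.0 + 3.0 * x
        B = rcs_basis(x, np.quantile(x, [0.1, 0.5, 0.9]))
        X = np.column_stack([np.ones(len(x)), B])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert abs(coef[2]) < 1e-8  # nonlinear term vanishes

    def test_linear_beyond_boundary_knots(self):
        """Second differences vanish outside the boundary knots."""
        knots = np.array([4.0, 5.0, 6.0])
        for xs in (np.linspace(0, 3.9, 40), np.linspace(6.1, 10, 40)):
            B = rcs_basis(xs, knots)
            for j in range(B.shape[1]):
                d2 = np.diff(B[:, j], 2)
                assert np.all(np.abs(d2) < 1e-8)

    def test_c2_continuity_at_interior_knot(self):
        knots = np.array([2.0, 5.0, 8.0])
        h = 1e-4
        for t in knots:
            xs = np.array([t - 2 * h, t - h, t, t + h, t + 2 * h])
            B = rcs_basis(xs, knots)
            for j in range(B.shape[1]):
                d2 = np.diff(B[:, j], 2) / h**2  # three second-difference estimates
                assert np.all(np.abs(np.diff(d2)) < 1e-2)

    @pytest.mark.parametrize("knots", [[1.0, 2.0], [3.0, 2.0, 5.0]])
    def test_bad_knots_raise(self, knots):
        with pytest.raises(ValueError):
            rcs_basis(np.arange(5.0), knots)

    def test_default_knots_are_quantiles(self):
        age = np.arange(20.0, 80.0)
        k = default_age_knots(age)
        assert len(k) == 3 and np.all(np.diff(k) > 0)


def test_build_covariates_round_trip_and_dropping():
    exam_df = pd.DataFrame(
        {
            "individual_id": ["a"] * 2 + ["b"] * 2 + ["c"] * 2,
            "exam": [1, 2] * 3,
            "sbp": [150.0, 120, 120, 120, np.nan, np.nan],
            "dbp": [95.0, 70, 70, 70, np.nan, np.nan],
            "meds": [False, False, False, False, np.nan, np.nan],
            "smokes": [True, False, np.nan, np.nan, False, False],
        }
    )
    subject_df = pd.DataFrame(
        {"individual_id": ["a", "b", "c"], "sex": [1, 0, 1], "age": [60.0, 44.0, 50.0]}
    )
    cov = build_covariates(exam_df, subject_df)
    # b is dropped (smoking never observed), c is dropped (no usable exam)
    assert list(cov["individual_id"]) == ["a"]
    row = cov.iloc[0]
    assert (row["Y"], row["age_ge55"], row["smoker_ever"], row["sex"]) == (1, 1, 1, 1)
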