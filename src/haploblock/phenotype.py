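"""Outcome and covariate derivation from longitudinal exam records.

The analysis outcome is "ever-hypertension": an individual is a case if, at
any of up to four examinations, systolic pressure exceeded 140 mmHg and
diastolic exceeded 90 mmHg (strict inequalities), or they were on
antihypertensive medication. Smoking is likewise collapsed to "ever-smoker",
and age is dichotomized at 55 years. A restricted-cubic-spline basis is
provided for exploring the age-outcome relation before dichotomizing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SBP_THRESHOLD = 140.0  # mmHg, strict
DBP_THRESHOLD = 90.0  # mmHg, strict
AGE_CUT = 55.0  # years


@dataclass
class ExamRecord:
    """One examination for one individual; ``None`` marks a missing field."""

    individual_id: str
    exam_index: int
    sbp: float | None = None
    dbp: float | None = None
    on_meds: bool | None = None
    smokes: bool | None = None


class NoUsableExamError(ValueError):
    """All exams for an individual are entirely missing."""


def _usable(exam: ExamRecord) -> bool:
    has_bp = exam.sbp is not None or exam.dbp is not None
    return has_bp or exam.on_meds is not None


def derive_hypertension(exams: list[ExamRecord], rule: str = "and") -> int:
    """Ever-hypertension outcome over up to four exams.

    An exam satisfies the blood-pressure criterion when ``sbp > 140`` and
    (``rule="and"``, the definition followed here) / or (``rule="or"``, the
    common clinical convention) ``dbp > 90``; medication use at any exam also
    qualifies. Missing fields never satisfy a criterion.
    """
    if rule not in ("and", "or"):
        raise ValueError(f"rule must be 'and' or 'or', got {rule!r}")
    if not any(_usable(e) for e in exams):
        raise NoUsableExamError("no usable exam")
    for exam in exams:
        sbp_high = exam.sbp is not None and exam.sbp > SBP_THRESHOLD
        dbp_high = exam.dbp is not None and exam.dbp > DBP_THRESHOLD
        bp = (sbp_high and dbp_high) if rule == "and" else (sbp_high or dbp_high)
        if bp or exam.on_meds is True:
            return 1
    return 0


def derive_smoker_ever(exams: list[ExamRecord]) -> int | None:
    """1 if smoking was reported at any exam; ``None`` if never observed."""
    seen = [e.smokes for e in exams if e.smokes is not None]
    if not seen:
        return None
    return int(any(seen))


def dichotomize_age(age_years: float, cut: float = AGE_CUT) -> int:
    """1 iff ``age_years >= cut`` (55 by default)."""
    if age_years < 0:
        raise ValueError(f"negative age {age_years}")
    return int(age_years >= cut)


def rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted cubic spline design columns (Harrell parameterization).

    Returns an ``(n, k-1)`` matrix whose first column is ``x`` and whose
    remaining ``k-2`` columns are the restricted cubic terms; the implied fit
    is linear beyond the boundary knots (zero second derivative outside).
    Nonlinear terms are scaled by the squared knot range for conditioning.
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    k = len(knots)
    if k < 3:
        raise ValueError("need at least 3 knots")
    if np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be strictly increasing")

    def cube_plus(v: np.ndarray) -> np.ndarray:
        return np.where(v > 0, v, 0.0) ** 3

    t_first, t_pen, t_last = knots[0], knots[-2], knots[-1]
    scale = (t_last - t_first) ** 2
    cols = [x]
    for j in range(k - 2):
        tj = knots[j]
        term = (
            cube_plus(x - tj)
            - cube_plus(x - t_pen) * (t_last - tj) / (t_last - t_pen)
            + cube_plus(x - t_last) * (t_pen - tj) / (t_last - t_pen)
        )
        cols.append(term / scale)
    return np.column_stack(cols)


def default_age_knots(age: np.ndarray) -> np.ndarray:
    """3 knots at the 5th/50th/95th age percentiles (small-sample default)."""
    return np.quantile(np.asarray(age, dtype=float), [0.05, 0.50, 0.95])


def _records_from_frame(exam_df: pd.DataFrame) -> dict[str, list[ExamRecord]]:
    def opt(v):
        return None if pd.isna(v) else v

    def opt_bool(v):
        return None if pd.isna(v) else bool(v)

    out: dict[str, list[ExamRecord]] = {}
    for row in exam_df.itertuples(index=False):
        rec = ExamRecord(
            individual_id=str(row.individual_id),
            exam_index=int(row.exam),
            sbp=opt(row.sbp),
            dbp=opt(row.dbp),
            on_meds=opt_bool(row.meds),
            smokes=opt_bool(row.smokes),
        )
        out.setdefault(rec.individual_id, []).append(rec)
    return out


def build_covariates(
    exam_df: pd.DataFrame,
    subject_df: pd.DataFrame,
    rule: str = "and",
    age_cut: float = AGE_CUT,
) -> pd.DataFrame:
    """Derive the per-subject covariate table used by all association models.

    ``exam_df`` has one row per individual-exam (columns ``individual_id,
    exam, sbp, dbp, meds, smokes``); ``subject_df`` has one row per
    individual (``individual_id, sex, age``). Individuals whose outcome or
    smoking status cannot be determined are dropped with a logged count.
    Returns columns ``individual_id, Y, age_years, age_ge55, sex,
    smoker_ever, pc1`` (``pc1`` filled later by the stratification step).
    """
    by_ind = _records_from_frame(exam_df)
    rows = []
    n_dropped = 0
    for subj in subject_df.itertuples(index=False):
        iid = str(subj.individual_id)
        exams = by_ind.get(iid, [])
        try:
            y = derive_hypertension(exams, rule=rule)
        except NoUsableExamError:
            n_dropped += 1
            continue
        smoker = derive_smoker_ever(exams)
        if smoker is None or pd.isna(subj.age) or pd.isna(subj.sex):
            n_dropped += 1
            continue
        age = float(subj.age)
        rows.append(
            {
                "individual_id": iid,
                "Y": y,
                "age_years": age,
                "age_ge55": dichotomize_age(age, cut=age_cut),
                "sex": int(subj.sex),
                "smoker_ever": smoker,
                "pc1": np.nan,
            }
        )
    if n_dropped:
        logger.info("dropped %d individuals with undeterminable outcome/covariates", n_dropped)
    return pd.DataFrame(
        rows,
        columns=["individual_id", "Y", "age_years", "age_ge55", "sex", "smoker_ever", "pc1"],
    )
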