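"""Omnibus and haplotype-specific association tests per block.

The omnibus test compares two nested logistic models by likelihood ratio:

  full:    logit P(Y=1) = b0 + b1' X_hap + b2 age_ge55 + b3 sex + b4 smoker + b5 pc1
  reduced: the same without the haplotype dosage columns X_hap,

with chi-square reference on df = number of haplotype columns. When the
omnibus test is significant, per-haplotype Wald tests within the full joint
model identify the specific haplotype, judged against a per-block Bonferroni
threshold 0.05 / number of haplotypes tested. Expected dosages are treated
as fixed covariates (expectation substitution); the extra uncertainty from
phase inference is not propagated — a known property of the two-stage
approach.

A permutation test for the omnibus statistic is provided with the caveat
that permuting outcomes breaks the covariate and population structure, so
permutation p-values need not match the asymptotic ones; an option to
permute within age strata partially mitigates this.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .containers import Block, HaploDesign
from .logistic import LogisticFit, fit_logistic

DEFAULT_COVARIATES = ["age_ge55", "sex", "smoker_ever", "pc1"]


@dataclass
class OmnibusResult:
    loglik_full: float
    loglik_reduced: float
    lrt_stat: float
    df: int
    p_value: float
    n_haplotype_columns: int
    converged: bool = True
    block: Block | None = None


@dataclass
class HaplotypeEffect:
    haplotype: str
    or_estimate: float
    ci95: tuple[float, float]
    p_value: float
    frequency: float


def _model_matrices(
    design: HaploDesign, covariates: pd.DataFrame, covariate_cols: list[str] | None
):
    cols = covariate_cols or [c for c in DEFAULT_COVARIATES if c in covariates.columns]
    cov = covariates.set_index("individual_id").loc[design.individuals]
    if cov[cols + ["Y"]].isna().any().any():
        keep = ~cov[cols + ["Y"]].isna().any(axis=1)
        cov = cov[keep]
        hap = design.values[np.asarray(keep)]
    else:
        hap = design.values
    y = cov["Y"].to_numpy(dtype=float)
    Z = cov[cols].to_numpy(dtype=float)
    n = len(y)
    X_full = np.column_stack([np.ones(n), hap, Z])
    X_red = np.column_stack([np.ones(n), Z])
    return y, X_full, X_red, hap.shape[1]


def omnibus_lrt(
    design: HaploDesign,
    covariates: pd.DataFrame,
    y: np.ndarray | None = None,
    covariate_cols: list[str] | None = None,
) -> OmnibusResult:
    """Likelihood-ratio test of all haplotype columns in a block.

    ``covariates`` carries ``individual_id``, ``Y`` and the adjustment
    columns; both nested models are fit on the same complete-case rows.
    """
    yv, X_full, X_red, k = _model_matrices(design, covariates, covariate_cols)
    if y is not None:
        yv = np.asarray(y, dtype=float)
    fit_red = fit_logistic(yv, X_red)
    if k == 0:
        return OmnibusResult(
            loglik_full=fit_red.loglik,
            loglik_reduced=fit_red.loglik,
            lrt_stat=0.0,
            df=0,
            p_value=1.0,
            n_haplotype_columns=0,
            converged=fit_red.converged,
        )
    fit_full = fit_logistic(yv, X_full)
    stat = 2.0 * (fit_full.loglik - fit_red.loglik)
    if stat < -1e-8:
        raise RuntimeError("full-model log-likelihood below reduced model")
    stat = max(stat, 0.0)
    converged = fit_full.converged and fit_red.converged
    p = float(chi2.sf(stat, df=k)) if converged else float("nan")
    return OmnibusResult(
        loglik_full=fit_full.loglik,
        loglik_reduced=fit_red.loglik,
        lrt_stat=float(stat),
        df=k,
        p_value=p,
        n_haplotype_columns=k,
        converged=converged,
    )


def haplotype_specific_tests(
    design: HaploDesign,
    covariates: pd.DataFrame,
    covariate_cols: list[str] | None = None,
    alpha_family: float = 0.05,
) -> tuple[list[HaplotypeEffect], float]:
    """Per-haplotype Wald tests within the full joint model.

    Returns one effect per haplotype dosage column plus the per-block
    Bonferroni threshold ``alpha_family / n_columns``.
    """
    yv, X_full, _, k = _model_matrices(design, covariates, covariate_cols)
    if k == 0:
        return [], alpha_family
    fit: LogisticFit = fit_logistic(yv, X_full)
    threshold = bonferroni_threshold(alpha_family, k)
    effects = []
    for j, label in enumerate(design.columns, start=1):
        or_est, lo, hi = fit.or_ci(j)
        effects.append(
            HaplotypeEffect(
                haplotype=label,
                or_estimate=or_est,
                ci95=(lo, hi),
                p_value=fit.wald_p(j) if fit.converged else float("nan"),
                frequency=float(design.frequencies.get(label, float("nan"))),
            )
        )
    return effects, threshold


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise threshold ``alpha / n_tests``."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def permutation_test(
    design: HaploDesign,
    covariates: pd.DataFrame,
    B: int = 999,
    seed: int | None = None,
    stratify_by: str | None = None,
    covariate_cols: list[str] | None = None,
) -> float:
    """Permutation p-value for the omnibus LRT statistic.

    Outcomes are permuted against the whole design row (optionally within
    strata of ``stratify_by``); p = (1 + #{perm stat >= observed}) / (B+1).
    """
    if B < 0:
        raise ValueError("B must be >= 0")
    if seed is None:
        raise ValueError("a seed is required for the permutation test")
    rng = np.random.default_rng(seed)
    yv, X_full, X_red, k = _model_matrices(design, covariates, covariate_cols)

    def stat_for(y):
        s = 2.0 * (fit_logistic(y, X_full).loglik - fit_logistic(y, X_red).loglik)
        return max(s, 0.0)

    observed = stat_for(yv)
    if B == 0:
        return 1.0
    if stratify_by is not None:
        cov = covariates.set_index("individual_id").loc[design.individuals]
        strata = cov[stratify_by].to_numpy()
    else:
        strata = None
    n_ge = 0
    for _ in range(B):
        if strata is None:
            y_perm = rng.permutation(yv)
        else:
            y_perm = yv.copy()
            for s in np.unique(strata):
                idx = np.where(strata == s)[0]
                y_perm[idx] = y_perm[rng.permutation(idx)]
        if stat_for(y_perm) >= observed - 1e-12:
            n_ge += 1
    return (1 + n_ge) / (B + 1)


def interaction_model(
    design: HaploDesign,
    covariates: pd.DataFrame,
    interact_with: str = "age_ge55",
    covariate_cols: list[str] | None = None,
) -> OmnibusResult:
    """LRT for haplotype-by-covariate interaction columns.

    Compares the main-effects model plus ``hap x interact_with`` products
    against the main-effects model; df = number of haplotype columns.
    Degenerate strata (all-zero interaction columns) surface as rank errors.
    """
    cols = covariate_cols or [c for c in DEFAULT_COVARIATES if c in covariates.columns]
    if interact_with not in cols:
        raise ValueError(f"{interact_with!r} not among covariates")
    yv, X_main, _, k = _model_matrices(design, covariates, cols)
    if k == 0:
        raise ValueError("no haplotype columns to interact")
    cov = covariates.set_index("individual_id").loc[design.individuals]
    z = cov[interact_with].to_numpy(dtype=float)
    inter = design.values * z[:, None]
    X_int = np.column_stack([X_main, inter])
    fit_main = fit_logistic(yv, X_main)
    fit_int = fit_logistic(yv, X_int)
    stat = max(2.0 * (fit_int.loglik - fit_main.loglik), 0.0)
    converged = fit_int.converged and fit_main.converged
    return OmnibusResult(
        loglik_full=fit_int.loglik,
        loglik_reduced=fit_main.loglik,
        lrt_stat=float(stat),
        df=k,
        p_value=float(chi2.sf(stat, df=k)) if converged else float("nan"),
        n_haplotype_columns=k,
        converged=converged,
    )
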