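"""Per-SNP logistic association scan with covariate and ancestry adjustment.

Each SNP enters an additive-dosage logistic model
``logit P(Y=1) = b0 + b_snp * g + b * (age_ge55, sex, smoker_ever, pc1)``
fit on the individuals called at that SNP (complete-case per SNP). Results
report the Wald odds ratio, 95% CI and p-value; SNPs whose fit fails to
converge (e.g. separation) are flagged rather than dropped. Candidate SNPs
for haplotype analysis are those with p below the nominal 5e-4 threshold.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix
from .logistic import fit_logistic

CANDIDATE_ALPHA = 5e-4
COVARIATE_COLS = ["age_ge55", "sex", "smoker_ever", "pc1"]


def covariate_matrix(covariates: pd.DataFrame, cols: list[str] | None = None) -> np.ndarray:
    cols = cols or [c for c in COVARIATE_COLS if c in covariates.columns]
    return covariates[cols].to_numpy(dtype=float)


def snp_scan(
    G: GenotypeMatrix,
    covariates: pd.DataFrame,
    covariate_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Scan all SNPs; returns snp_id, or, ci, p, converged, n_used.

    ``covariates`` must be row-aligned with ``G.individuals`` and contain
    ``Y`` plus the adjustment columns (missing ones are skipped).
    """
    if list(covariates["individual_id"]) != list(G.individuals):
        raise ValueError("covariate rows must align with genotype individuals")
    y_all = covariates["Y"].to_numpy(dtype=float)
    cols = covariate_cols or [c for c in COVARIATE_COLS if c in covariates.columns]
    Z = covariates[cols].to_numpy(dtype=float)
    if np.isnan(Z).any():
        raise ValueError("covariates contain missing values; drop those individuals first")

    rows = []
    for j in range(G.n_snps):
        g = G.values[:, j].astype(float)
        ok = g != MISSING
        dosage = g[ok]
        if len(np.unique(dosage)) < 2:
            raise ValueError(f"monomorphic SNP {G.snps['id'][j]!r}; QC should remove it")
        X = np.column_stack([np.ones(ok.sum()), dosage, Z[ok]])
        fit = fit_logistic(y_all[ok], X)
        or_est, lo, hi = fit.or_ci(1)
        rows.append(
            {
                "snp_id": G.snps["id"][j],
                "chrom": G.snps["chrom"][j],
                "pos": G.snps["pos"][j],
                "or_estimate": or_est,
                "ci_low": lo,
                "ci_high": hi,
                "p_value": fit.wald_p(1) if fit.converged else np.nan,
                "converged": fit.converged,
                "n_used": fit.n_used,
            }
        )
    return pd.DataFrame(rows)


def select_candidates(results: pd.DataFrame, alpha: float = CANDIDATE_ALPHA) -> pd.DataFrame:
    """Nominally significant SNPs (p < alpha), sorted by genomic position."""
    if results.empty:
        return results
    hits = results[results["p_value"] < alpha]
    return hits.sort_values(["chrom", "pos"]).reset_index(drop=True)
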