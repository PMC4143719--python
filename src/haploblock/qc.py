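"""Case-control genotype quality control.

The filter chain runs in a fixed order, each step on the survivors of the
previous one: (1) drop individuals with genotype missing rate above 0.05;
(2) drop SNPs with minor allele frequency below 0.1; (3) drop SNPs with
missing rate above 0.05; (4) drop SNPs failing an exact Hardy-Weinberg test
at 1e-6. Heterozygosity-rate outliers (beyond +/-3 SD of the mean rate) are
reported but not removed by default. Boundary values survive every filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix

DEFAULT_THRESHOLDS = {
    "ind_miss": 0.05,
    "maf": 0.1,
    "snp_miss": 0.05,
    "hwe": 1e-6,
    "het_sd": 3.0,
}


class EmptySurvivorsError(ValueError):
    """A QC step removed everything; carries the step name."""


@dataclass
class QcReport:
    """Per-step exclusion counts plus per-individual heterozygosity rates."""

    steps: pd.DataFrame = field(default_factory=pd.DataFrame)
    het_rates: pd.Series = field(default_factory=pd.Series)
    het_flagged: list[str] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        self.steps.to_csv(path, sep="\t", index=False)


def individual_missing_rate(G: GenotypeMatrix) -> np.ndarray:
    """Fraction of missing calls per individual over the current SNPs."""
    if G.n_snps == 0:
        raise ValueError("empty genotype matrix")
    return (G.values == MISSING).mean(axis=1)


def snp_missing_rate(G: GenotypeMatrix) -> np.ndarray:
    if G.n_individuals == 0:
        raise ValueError("empty genotype matrix")
    return (G.values == MISSING).mean(axis=0)


def maf(G: GenotypeMatrix, snp_index: int) -> float:
    """Minor allele frequency at one SNP; missing calls excluded."""
    col = G.values[:, snp_index]
    obs = col[col != MISSING]
    if obs.size == 0:
        raise ValueError("all calls missing at SNP")
    p = obs.sum() / (2 * obs.size)
    return float(min(p, 1 - p))


def all_mafs(G: GenotypeMatrix) -> np.ndarray:
    vals = G.values
    obs = vals != MISSING
    n_obs = obs.sum(axis=0)
    if np.any(n_obs == 0):
        raise ValueError("SNP with all calls missing; filter by missingness first")
    p = np.where(vals == MISSING, 0, vals).sum(axis=0) / (2 * n_obs)
    return np.minimum(p, 1 - p)


def hwe_exact_test(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts no more probable than the observed one under the
    exact HWE distribution (Wigginton-Cutler-Abecasis recurrence).
    """
    if min(n_hom_major, n_het, n_hom_minor) < 0:
        raise ValueError("negative genotype count")
    n = n_hom_major + n_het + n_hom_minor
    if n == 0:
        raise ValueError("no genotypes")
    rare = 2 * min(n_hom_major, n_hom_minor) + n_het  # minor allele count
    if rare == 0:
        return 1.0

    # probabilities over all het counts with the same parity as `rare`
    n_het_values = np.arange(rare % 2, rare + 1, 2)
    probs = np.zeros(len(n_het_values))
    # start at the mode-ish midpoint and recurse both ways
    mid = rare * (2 * n - rare) // (2 * n)
    if mid % 2 != rare % 2:
        mid += 1
    mid_idx = int(np.searchsorted(n_het_values, mid))
    probs[mid_idx] = 1.0
    # downward: P(h-2)/P(h) = h(h-1) / (4 (rr+1)(cc+1)) with rr,cc homs at h
    for i in range(mid_idx, 0, -1):
        h = n_het_values[i]
        rr = (rare - h) // 2  # rare homozygotes
        cc = n - h - rr  # common homozygotes
        probs[i - 1] = probs[i] * h * (h - 1) / (4.0 * (rr + 1) * (cc + 1))
    # upward: P(h+2)/P(h) = 4 rr cc / ((h+2)(h+1))
    for i in range(mid_idx, len(n_het_values) - 1):
        h = n_het_values[i]
        rr = (rare - h) // 2
        cc = n - h - rr
        probs[i + 1] = probs[i] * 4.0 * rr * cc / ((h + 2.0) * (h + 1.0))
    probs /= probs.sum()
    obs_idx = int(np.searchsorted(n_het_values, n_het))
    p_obs = probs[obs_idx]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def hwe_pvalues(G: GenotypeMatrix) -> np.ndarray:
    out = np.empty(G.n_snps)
    for j in range(G.n_snps):
        col = G.values[:, j]
        obs = col[col != MISSING]
        out[j] = hwe_exact_test(
            int((obs == 0).sum()), int((obs == 1).sum()), int((obs == 2).sum())
        )
    return out


def heterozygosity_rates(G: GenotypeMatrix) -> np.ndarray:
    """Per-individual heterozygote fraction among non-missing calls."""
    vals = G.values
    n_obs = (vals != MISSING).sum(axis=1)
    with np.errstate(invalid="ignore"):
        return np.where(n_obs > 0, (vals == 1).sum(axis=1) / n_obs, np.nan)


def heterozygosity_outliers(G: GenotypeMatrix, k_sd: float = 3.0) -> list[str]:
    """Individuals whose het rate lies beyond ``k_sd`` sample SDs of the mean."""
    if G.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    rates = heterozygosity_rates(G)
    sd = np.std(rates, ddof=1)
    if sd == 0 or not np.isfinite(sd):
        return []
    flag = np.abs(rates - rates.mean()) > k_sd * sd
    return [iid for iid, f in zip(G.individuals, flag) if f]


def run_qc_pipeline(
    G: GenotypeMatrix,
    thresholds: dict | None = None,
    remove_het_outliers: bool = False,
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply the ordered QC chain and return survivors plus a report.

    Order: individual missingness > ``ind_miss`` -> MAF < ``maf`` ->
    SNP missingness > ``snp_miss`` -> HWE p < ``hwe``. Heterozygosity
    outliers are flagged; they are removed only when ``remove_het_outliers``.
    """
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        th.update(thresholds)

    rows = []

    def record(step, threshold, n_ind_rm, n_snp_rm, g):
        rows.append(
            {
                "step": step,
                "threshold": threshold,
                "n_individuals_removed": n_ind_rm,
                "n_snps_removed": n_snp_rm,
                "individuals_remaining": g.n_individuals,
                "snps_remaining": g.n_snps,
            }
        )

    def check(g, step):
        if g.n_individuals == 0 or g.n_snps == 0:
            raise EmptySurvivorsError(f"no survivors after step {step!r}")

    # 1. individual missingness (strictly above threshold removed)
    keep_ind = individual_missing_rate(G) <= th["ind_miss"]
    g = G.subset_individuals(keep_ind)
    record("individual_missingness", th["ind_miss"], int((~keep_ind).sum()), 0, g)
    check(g, "individual_missingness")

    # 2. MAF (strictly below threshold removed); all-missing SNPs also go here
    n_obs = (g.values != MISSING).sum(axis=0)
    callable_snp = n_obs > 0
    mafs = np.zeros(g.n_snps)
    if callable_snp.any():
        vals = np.where(g.values == MISSING, 0, g.values)
        p = np.divide(
            vals.sum(axis=0), 2 * n_obs, out=np.zeros(g.n_snps), where=callable_snp
        )
        mafs = np.minimum(p, 1 - p)
    keep_snp = callable_snp & (mafs >= th["maf"])
    g2 = g.subset_snps(keep_snp)
    record("maf", th["maf"], 0, int((~keep_snp).sum()), g2)
    check(g2, "maf")

    # 3. SNP missingness (strictly above threshold removed)
    keep_snp = snp_missing_rate(g2) <= th["snp_miss"]
    g3 = g2.subset_snps(keep_snp)
    record("snp_missingness", th["snp_miss"], 0, int((~keep_snp).sum()), g3)
    check(g3, "snp_missingness")

    # 4. HWE exact test (strictly below threshold removed)
    keep_snp = hwe_pvalues(g3) >= th["hwe"]
    g4 = g3.subset_snps(keep_snp)
    record("hwe", th["hwe"], 0, int((~keep_snp).sum()), g4)
    check(g4, "hwe")

    # 5. heterozygosity outliers: reported, removal optional
    flagged = heterozygosity_outliers(g4, k_sd=th["het_sd"]) if g4.n_individuals >= 2 else []
    if remove_het_outliers and flagged:
        keep_ind = ~np.isin(np.asarray(g4.individuals, dtype=object), flagged)
        g5 = g4.subset_individuals(keep_ind)
    else:
        g5 = g4
    record("heterozygosity", th["het_sd"], g4.n_individuals - g5.n_individuals, 0, g5)
    check(g5, "heterozygosity")

    report = QcReport(
        steps=pd.DataFrame(rows),
        het_rates=pd.Series(heterozygosity_rates(g4), index=list(g4.individuals)),
        het_flagged=flagged,
    )
    return g5, report
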