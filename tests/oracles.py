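"""Independent oracles used by the tests.

Each oracle is a deliberately naive computation (enumeration, grid search,
or an external fitter) kept independent of the implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np


def hwe_enumeration_oracle(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact HWE p by brute-force enumeration of all tables with the same
    sample size and allele counts; probability of a table is the conditional
    multinomial weight ``C(n, a) C(n-a, b) 2^b``."""
    n = n_hom_major + n_het + n_hom_minor
    n_a = 2 * n_hom_major + n_het  # major allele count
    weights = {}
    for b in range(n + 1):
        rem = n_a - b
        if rem < 0 or rem % 2:
            continue
        a = rem // 2
        c = n - a - b
        if c < 0:
            continue
        weights[b] = math.comb(n, a) * math.comb(n - a, b) * 2**b
    total = sum(weights.values())
    w_obs = weights[n_het]
    return sum(w for w in weights.values() if w <= w_obs * (1 + 1e-12)) / total


def two_snp_em_grid_oracle(geno: np.ndarray, step: float = 1e-4) -> dict[str, float]:
    """Maximum-likelihood two-SNP haplotype frequencies by grid search.

    Allele frequencies are fixed at their (marginal-MLE) sample values; the
    free parameter p11 is scanned on a grid. Only the double-heterozygote
    genotype class has phase ambiguity: P = 2(p11*p00 + p10*p01); all other
    classes are products of the two unordered gamete probabilities.
    """
    geno = np.asarray(geno)
    p_a = geno[:, 0].mean() / 2.0
    p_b = geno[:, 1].mean() / 2.0
    counts = np.zeros((3, 3))
    for g1, g2 in geno:
        counts[g1, g2] += 1

    def loglik(p11):
        p10 = p_a - p11
        p01 = p_b - p11
        p00 = 1 - p_a - p_b + p11
        h = {(0, 0): p00, (0, 1): p01, (1, 0): p10, (1, 1): p11}
        ll = 0.0
        for g1 in range(3):
            for g2 in range(3):
                if counts[g1, g2] == 0:
                    continue
                prob = 0.0
                for a1 in (0, 1):
                    for b1 in (0, 1):
                        a2, b2 = g1 - a1, g2 - b1
                        if a2 in (0, 1) and b2 in (0, 1):
                            prob += h[(a1, b1)] * h[(a2, b2)]
                ll += counts[g1, g2] * np.log(max(prob, 1e-300))
        return ll

    lo = max(0.0, p_a + p_b - 1.0)
    hi = min(p_a, p_b)
    grid = np.arange(lo, hi + step, step)
    lls = np.array([loglik(p) for p in grid])
    p11 = float(grid[np.argmax(lls)])
    return {
        "11": p11,
        "10": p_a - p11,
        "01": p_b - p11,
        "00": 1 - p_a - p_b + p11,
    }


def logistic_mle_oracle(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Independent MLE via statsmodels Newton fitter."""
    import statsmodels.api as sm

    return np.asarray(sm.Logit(y, X).fit(disp=0, method="newton").params)


def eq3_posterior_oracle(
    genotype: tuple[int, ...], freqs: dict[str, float]
) -> dict[tuple[str, str], float]:
    """Diplotype posterior by direct enumeration over all ordered pairs."""
    haps = list(freqs)
    weights: dict[tuple[str, str], float] = {}
    for h1 in haps:
        for h2 in haps:
            ok = all(
                g < 0 or int(a) + int(b) == g
                for a, b, g in zip(h1, h2, genotype)
            )
            if ok:
                key = (h1, h2) if h1 <= h2 else (h2, h1)
                weights[key] = weights.get(key, 0.0) + freqs[h1] * freqs[h2]
    total = sum(weights.values())
    return {k: v / total for k, v in weights.items()}
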