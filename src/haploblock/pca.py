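"""Ancestry principal components for stratification adjustment.

EIGENSTRAT-style: each SNP column is centered by its mean and scaled by
``sqrt(p(1-p))`` with the Bayesian posterior allele frequency
``p = (1 + sum g) / (2 + 2n)``; missing entries are mean-imputed (zero after
centering). Components are eigenvectors of the individual-by-individual
covariance of the normalized matrix; by default one component is extracted
and used as the ancestry covariate in the association models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import MISSING, GenotypeMatrix


@dataclass
class PcResult:
    components: np.ndarray  # (n, k) scores, unit-norm eigenvectors
    eigenvalues: np.ndarray  # non-increasing
    snps_used: list[str]


def normalize_genotypes(G: GenotypeMatrix) -> np.ndarray:
    """Center and variance-scale the genotype matrix for PCA."""
    vals = G.values.astype(float)
    obs = G.values != MISSING
    n_obs = obs.sum(axis=0)
    if np.any(n_obs == 0):
        raise ValueError("SNP with no observed calls")
    sums = np.where(obs, vals, 0.0).sum(axis=0)
    mean = sums / n_obs
    p_hat = (1.0 + sums) / (2.0 + 2.0 * n_obs)
    mono = (mean == 0.0) | (mean == 2.0)
    if mono.any():
        raise ValueError(f"{int(mono.sum())} monomorphic SNP(s); apply MAF filter first")
    X = (vals - mean) / np.sqrt(p_hat * (1.0 - p_hat))
    X[~obs] = 0.0  # mean imputation
    return X


def compute_pcs(X: np.ndarray, k: int = 1) -> PcResult:
    """Top-k principal components of the normalized genotype matrix.

    Sign convention: each component is flipped so its largest-magnitude
    score is positive, making results reproducible across linear-algebra
    backends.
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    if n < 2 or m < 1:
        raise ValueError("need at least 2 individuals and 1 SNP")
    if k > min(n, m):
        raise ValueError(f"k={k} exceeds min(n, m)={min(n, m)}")
    cov = (X @ X.T) / m
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1][:k]
    eigvals = np.clip(w[order], 0.0, None)
    comps = v[:, order]
    for j in range(k):
        i_max = np.argmax(np.abs(comps[:, j]))
        if comps[i_max, j] < 0:
            comps[:, j] = -comps[:, j]
    return PcResult(components=comps, eigenvalues=eigvals, snps_used=[])


def ancestry_pcs(G: GenotypeMatrix, k: int = 1) -> PcResult:
    """Normalize and extract components in one call."""
    res = compute_pcs(normalize_genotypes(G), k=k)
    res.snps_used = list(G.snps["id"])
    return res
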