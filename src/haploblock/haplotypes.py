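"""EM haplotype-frequency estimation and diplotype posteriors.

Within an LD block, an individual's unphased genotype is compatible with a
set of unordered haplotype pairs (2^(h-1) pairs for h heterozygous sites;
missing sites are marginalized over). Population haplotype frequencies are
estimated by expectation-maximization over these compatible sets, assuming
random union of gametes (HWE) within the block:

  E-step: Pr(h_m, h_n | G_i) ∝ Pr(G_i | h_m, h_n) * p_m * p_n
          (the weight is doubled for heterozygous pairs m != n, since both
          orderings of an unordered pair are distinct gamete unions);
  M-step: p_h <- expected count of h over all individuals / 2n.

The resulting posteriors also supply the expected haplotype dosages used as
regression covariates (haplotype trend regression / expectation
substitution): dosage_i(h) = sum over pairs Pr(pair|G_i) * count of h.
"""

from __future__ import annotations

import itertools
import logging
from functools import lru_cache

import numpy as np

from .containers import MISSING, RARE_LABEL, DiplotypeDist, HaploDesign, HaplotypeTable

logger = logging.getLogger(__name__)

MAX_BLOCK_WIDTH = 25

_SITE_OPTIONS = {
    0: ((0, 0),),
    2: ((1, 1),),
    1: ((0, 1), (1, 0)),
    MISSING: ((0, 0), (0, 1), (1, 0), (1, 1)),
}


@lru_cache(maxsize=100_000)
def compatible_pairs(pattern: tuple[int, ...]) -> tuple[tuple[str, str], ...]:
    """Unordered haplotype pairs compatible with one genotype pattern.

    ``pattern`` holds per-SNP minor-allele counts (0/1/2, -1 missing). Each
    returned pair ``(h_m, h_n)`` satisfies ``h_m <= h_n`` lexicographically
    and sums to the genotype at every non-missing site.
    """
    if len(pattern) > MAX_BLOCK_WIDTH:
        raise ValueError(
            f"enumerate-infeasible block: width {len(pattern)} > {MAX_BLOCK_WIDTH}"
        )
    options = [_SITE_OPTIONS[g] for g in pattern]
    seen: set[tuple[str, str]] = set()
    for combo in itertools.product(*options):
        h1 = "".join(str(a) for a, _ in combo)
        h2 = "".join(str(b) for _, b in combo)
        seen.add((h1, h2) if h1 <= h2 else (h2, h1))
    return tuple(sorted(seen))


def _pattern_groups(geno: np.ndarray):
    """Unique genotype rows with multiplicities (EM cost is per pattern)."""
    geno = np.asarray(geno)
    patterns, inverse, counts = np.unique(
        geno, axis=0, return_inverse=True, return_counts=True
    )
    return [tuple(int(g) for g in row) for row in patterns], inverse, counts


def _allele_freq_init(geno: np.ndarray, haps: list[str]) -> np.ndarray:
    """Product-of-allele-frequency initialization over the candidate set."""
    obs = geno != MISSING
    n_obs = obs.sum(axis=0)
    p = np.where(
        n_obs > 0, np.where(obs, geno, 0).sum(axis=0) / np.maximum(2 * n_obs, 1), 0.5
    )
    p = np.clip(p, 1e-6, 1 - 1e-6)
    init = np.empty(len(haps))
    for k, h in enumerate(haps):
        a = np.frombuffer(h.encode(), dtype=np.uint8) - ord("0")
        init[k] = np.prod(np.where(a == 1, p, 1 - p))
    init = np.maximum(init, 1e-9)
    return init / init.sum()


def em_haplotype_frequencies(
    geno: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 1000,
    n_restarts: int = 1,
    rng: np.random.Generator | None = None,
) -> HaplotypeTable:
    """Estimate within-block haplotype frequencies by EM.

    ``geno`` is the ``(n, w)`` block genotype slice. The candidate haplotype
    set is the union of haplotypes appearing in any individual's compatible
    pairs. Convergence when the max absolute frequency change drops below
    ``tol``; the observed-data log-likelihood is checked to be non-decreasing
    at every iteration. Haplotypes with final frequency below 1e-12 are
    pruned. Extra ``n_restarts - 1`` runs from Dirichlet-perturbed starts
    guard against local optima (the likelihood is typically unimodal for the
    narrow blocks this package targets); the best log-likelihood wins.
    """
    geno = np.asarray(geno)
    if geno.ndim != 2 or geno.shape[0] < 1 or geno.shape[1] < 1:
        raise ValueError("need an (n, w) genotype slice with n,w >= 1")
    if geno.shape[1] > MAX_BLOCK_WIDTH:
        raise ValueError(
            f"enumerate-infeasible block: width {geno.shape[1]} > {MAX_BLOCK_WIDTH}"
        )
    patterns, _, counts = _pattern_groups(geno)
    pair_lists = [compatible_pairs(p) for p in patterns]
    haps = sorted({h for pairs in pair_lists for pair in pairs for h in pair})
    idx = {h: k for k, h in enumerate(haps)}
    K = len(haps)
    n = geno.shape[0]

    # per-pattern index arrays for vectorized E-steps
    packed = []
    for pairs, c in zip(pair_lists, counts):
        m = np.array([idx[a] for a, _ in pairs])
        nn = np.array([idx[b] for _, b in pairs])
        mult = np.where(m == nn, 1.0, 2.0)
        packed.append((m, nn, mult, float(c)))

    def run(p0: np.ndarray):
        p = p0.copy()
        ll = -np.inf
        it = 0
        converged = False
        for it in range(1, max_iter + 1):
            counts_new = np.zeros(K)
            ll_new = 0.0
            for m, nn, mult, c in packed:
                w = mult * p[m] * p[nn]
                s = w.sum()
                if s <= 0.0:
                    w = mult / mult.sum()
                    s = 1e-300
                post = w / w.sum()
                ll_new += c * np.log(s)
                np.add.at(counts_new, m, post * c)
                np.add.at(counts_new, nn, post * c)
            if ll_new < ll - 1e-9:
                raise RuntimeError("EM log-likelihood decreased")
            p_new = counts_new / (2.0 * n)
            delta = np.max(np.abs(p_new - p))
            p, ll = p_new, ll_new
            if delta < tol:
                converged = True
                break
        return p, ll, it, converged

    starts = [_allele_freq_init(geno, haps)]
    if n_restarts > 1:
        rng = rng or np.random.default_rng(0)
        for _ in range(n_restarts - 1):
            starts.append(rng.dirichlet(np.ones(K)))

    best = None
    for p0 in starts:
        res = run(p0)
        if best is None or res[1] > best[1]:
            best = res
    p, ll, it, converged = best

    keep = p >= 1e-12
    haps_kept = [h for h, k in zip(haps, keep) if k]
    p_kept = p[keep]
    p_kept = p_kept / p_kept.sum()
    return HaplotypeTable(
        haplotypes=haps_kept, freqs=p_kept, loglik=float(ll), n_iter=it, converged=converged
    )


def diplotype_posteriors(
    geno: np.ndarray,
    table: HaplotypeTable,
    individuals: list[str] | None = None,
) -> list[DiplotypeDist]:
    """Posterior over compatible unordered haplotype pairs per individual.

    Pairs are restricted to haplotypes with positive estimated frequency;
    an individual compatible with no such pair falls back to a uniform
    posterior over its full enumerated compatible set (logged).
    """
    geno = np.asarray(geno)
    if individuals is None:
        individuals = [str(i) for i in range(geno.shape[0])]
    freq = dict(zip(table.haplotypes, table.freqs))
    out = []
    n_fallback = 0
    for iid, row in zip(individuals, geno):
        pairs = compatible_pairs(tuple(int(g) for g in row))
        weights = []
        kept = []
        for a, b in pairs:
            pa, pb = freq.get(a, 0.0), freq.get(b, 0.0)
            w = (1.0 if a == b else 2.0) * pa * pb
            if w > 0:
                kept.append((a, b))
                weights.append(w)
        if not kept:
            n_fallback += 1
            kept = list(pairs)
            weights = [1.0] * len(kept)
        probs = np.asarray(weights, dtype=float)
        probs /= probs.sum()
        out.append(DiplotypeDist(individual_id=str(iid), pairs=kept, probs=probs))
    if n_fallback:
        logger.warning(
            "%d individual(s) incompatible with all positive-frequency haplotypes; "
            "uniform fallback posterior used",
            n_fallback,
        )
    return out


def expected_dosage_design(
    dists: list[DiplotypeDist],
    table: HaplotypeTable,
    reference: str | None = None,
    pool_below: float = 0.01,
) -> HaploDesign:
    """Expected-dosage design matrix for the haplotype regression models.

    Haplotypes with estimated frequency below ``pool_below`` are merged into
    a single ``rare`` column; the reference haplotype (most frequent by
    default, lexicographic tie-break) is omitted to avoid the dosages-sum-
    to-2 collinearity with the intercept.
    """
    freq = dict(zip(table.haplotypes, table.freqs))
    common = sorted(h for h, f in freq.items() if f >= pool_below)
    rare = sorted(h for h, f in freq.items() if f < pool_below)
    if reference is None:
        top = max(freq.values())
        reference = min(h for h, f in freq.items() if f == top)
    if reference not in freq:
        raise ValueError(f"reference haplotype {reference!r} not in table")
    if reference in rare:
        raise ValueError("reference haplotype is below the rare-pooling threshold")
    columns = [h for h in common if h != reference]
    # haplotypes outside the table (fallback posteriors) also pool into rare;
    # a rare column with negligible posterior mass would be an all-but-zero
    # regressor, so it is only emitted when it carries real mass
    rare_mass = float(sum(freq[h] for h in rare))
    need_rare = rare_mass > 1e-6 or any(
        h not in freq for d in dists for pair in d.pairs for h in pair
    )
    if need_rare:
        columns = columns + [RARE_LABEL]
    col_idx = {h: j for j, h in enumerate(columns) if h != RARE_LABEL}
    values = np.zeros((len(dists), len(columns)))
    for i, d in enumerate(dists):
        for (a, b), q in zip(d.pairs, d.probs):
            for h in (a, b):
                if h == reference or h in common and h not in col_idx:
                    continue
                j = col_idx.get(h)
                if j is None:
                    if not need_rare:
                        continue  # negligible remnant mass, no rare column
                    j = len(columns) - 1  # rare pool
                values[i, j] += q
    frequencies = {h: freq[h] for h in columns if h in freq}
    if need_rare:
        frequencies[RARE_LABEL] = rare_mass
    return HaploDesign(
        individuals=[d.individual_id for d in dists],
        columns=columns,
        values=values,
        reference=reference,
        frequencies=frequencies,
    )


def block_design(
    geno: np.ndarray,
    individuals: list[str] | None = None,
    pool_below: float = 0.01,
    tol: float = 1e-8,
) -> tuple[HaplotypeTable, HaploDesign]:
    """Convenience: EM, posteriors and design matrix for one block slice."""
    table = em_haplotype_frequencies(geno, tol=tol)
    dists = diplotype_posteriors(geno, table, individuals)
    design = expected_dosage_design(dists, table, pool_below=pool_below)
    return table, design
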