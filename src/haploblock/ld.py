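"""Pairwise linkage disequilibrium and haplotype-block construction.

Two block definitions are provided, mirroring the standard tooling defaults:

* the confidence-interval ("Gabriel") algorithm — SNP pairs are classified
  by a likelihood-based 90% CI on D'; a span is a block when its endpoint
  pair shows strong LD and at least 95% of informative inner pairs do;
* the four-gamete rule — a pair exhibiting all four two-locus haplotypes at
  frequency >= 0.01 implies historical recombination and splits blocks.

Two-SNP haplotype frequencies come from the same EM used for full blocks,
so D, D' and r^2 are defined on EM-estimated gamete frequencies. In
chromosome-wide mode, pairwise LD is only evaluated for SNPs within a
100-kb window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import MISSING, Block, GenotypeMatrix
from .haplotypes import em_haplotype_frequencies

GABRIEL_CI_LOW_STRONG = 0.70
GABRIEL_CI_HIGH_STRONG = 0.98
GABRIEL_CI_HIGH_RECOMB = 0.90
GABRIEL_FRAC_STRONG = 0.95
DEFAULT_WINDOW_BP = 100_000
FOUR_GAMETE_FREQ = 0.01

_DPRIME_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class PairLd:
    snp_i: int
    snp_j: int
    d: float
    d_prime: float
    r2: float
    dprime_ci: tuple[float, float]


def _pair_hap_freqs(gi: np.ndarray, gj: np.ndarray) -> tuple[np.ndarray, int]:
    """EM two-SNP haplotype frequencies [p00, p01, p10, p11] on complete cases."""
    ok = (gi != MISSING) & (gj != MISSING)
    sub = np.column_stack([gi[ok], gj[ok]])
    if sub.shape[0] == 0:
        raise ValueError("no individuals called at both SNPs")
    table = em_haplotype_frequencies(sub, tol=1e-10)
    freq = dict(zip(table.haplotypes, table.freqs))
    p = np.array([freq.get(h, 0.0) for h in ("00", "01", "10", "11")])
    return p, sub.shape[0]


def _genotype_counts(gi: np.ndarray, gj: np.ndarray) -> np.ndarray:
    ok = (gi != MISSING) & (gj != MISSING)
    counts = np.zeros((3, 3))
    for a, b in zip(gi[ok], gj[ok]):
        counts[a, b] += 1
    return counts


def _cell_probs(hap_freqs: np.ndarray) -> np.ndarray:
    """3x3 unphased genotype-class probabilities under random gamete union."""
    # haplotype order: 00, 01, 10, 11 -> (allele at SNP i, allele at SNP j)
    alleles = [(0, 0), (0, 1), (1, 0), (1, 1)]
    cells = np.zeros((3, 3))
    for (a1, b1), f1 in zip(alleles, hap_freqs):
        for (a2, b2), f2 in zip(alleles, hap_freqs):
            cells[a1 + a2, b1 + b2] += f1 * f2
    return cells


def _dprime_ci(
    counts: np.ndarray, p_a: float, p_b: float, sign: float
) -> tuple[float, float]:
    """Likelihood-profile 90% CI for D' on a 101-point grid.

    Allele frequencies are held at their estimates; for each grid value of
    D' (with the sign of the point estimate of D) the implied haplotype
    frequencies give a multinomial likelihood over the 3x3 genotype table.
    The interval endpoints cut 5% of normalized likelihood mass from each
    tail, following the HAPLOVIEW convention.
    """
    if sign >= 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    if d_max <= 0:
        return (0.0, 1.0)
    logls = np.empty(len(_DPRIME_GRID))
    for k, dp in enumerate(_DPRIME_GRID):
        d = (1.0 if sign >= 0 else -1.0) * dp * d_max
        hf = np.array(
            [
                (1 - p_a) * (1 - p_b) + d,
                (1 - p_a) * p_b - d,
                p_a * (1 - p_b) - d,
                p_a * p_b + d,
            ]
        )
        hf = np.clip(hf, 1e-12, None)
        hf = hf / hf.sum()
        logls[k] = float(np.sum(counts * np.log(_cell_probs(hf))))
    w = np.exp(logls - logls.max())
    w /= w.sum()
    csum = np.cumsum(w)
    low_idx = int(np.searchsorted(csum, 0.05, side="right"))
    tail = np.cumsum(w[::-1])
    high_idx = len(w) - 1 - int(np.searchsorted(tail, 0.05, side="right"))
    low_idx = min(low_idx, len(w) - 1)
    high_idx = max(high_idx, low_idx)
    return (float(_DPRIME_GRID[low_idx]), float(_DPRIME_GRID[high_idx]))


def pairwise_ld(G: GenotypeMatrix, i: int, j: int) -> PairLd:
    """D, D', r^2 and the D' confidence interval for one SNP pair."""
    gi, gj = G.values[:, i], G.values[:, j]
    ok = (gi != MISSING) & (gj != MISSING)
    for g, name in ((gi[ok], "first"), (gj[ok], "second")):
        if g.size == 0 or len(np.unique(g)) == 1 and g[0] in (0, 2):
            raise ValueError(f"{name} SNP monomorphic among shared non-missing calls")
    hf, _ = _pair_hap_freqs(gi, gj)
    p_a = hf[2] + hf[3]  # minor allele at SNP i
    p_b = hf[1] + hf[3]  # minor allele at SNP j
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise ValueError("monomorphic SNP in pair")
    d = hf[3] - p_a * p_b
    if d >= 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    d_prime = abs(d) / d_max if d_max > 0 else 0.0
    r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    counts = _genotype_counts(gi, gj)
    ci = _dprime_ci(counts, p_a, p_b, np.sign(d) if d != 0 else 1.0)
    return PairLd(
        snp_i=i,
        snp_j=j,
        d=float(d),
        d_prime=float(min(d_prime, 1.0)),
        r2=float(min(r2, 1.0)),
        dprime_ci=ci,
    )


def _n_gametes(gi: np.ndarray, gj: np.ndarray, freq_threshold: float) -> int:
    hf, _ = _pair_hap_freqs(gi, gj)
    return int(np.sum(hf >= freq_threshold))


def _chrom_ranges(G: GenotypeMatrix):
    chroms = G.snps["chrom"].to_numpy()
    start = 0
    for k in range(1, len(chroms) + 1):
        if k == len(chroms) or chroms[k] != chroms[start]:
            yield chroms[start], start, k
            start = k


def _make_block(G: GenotypeMatrix, chrom: str, indices: list[int], method: str) -> Block:
    pos = G.snps["pos"].to_numpy()
    return Block(
        chrom=str(chrom),
        snp_indices=np.asarray(indices),
        start_pos=int(pos[indices[0]]),
        end_pos=int(pos[indices[-1]]),
        method=method,
    )


def four_gamete_blocks(
    G: GenotypeMatrix, freq_threshold: float = FOUR_GAMETE_FREQ
) -> list[Block]:
    """Greedy left-to-right block extension under the four-gamete rule.

    A block grows while every SNP pair inside it shows at most three
    two-SNP haplotypes with EM frequency >= ``freq_threshold``; a pair
    exhibiting all four gametes starts a new block. Runs of fewer than two
    SNPs are not reported.
    """
    blocks: list[Block] = []
    vals = G.values
    for chrom, lo, hi in _chrom_ranges(G):
        current = [lo]
        for j in range(lo + 1, hi):
            ok = all(
                _n_gametes(vals[:, k], vals[:, j], freq_threshold) <= 3 for k in current
            )
            if ok:
                current.append(j)
            else:
                if len(current) >= 2:
                    blocks.append(_make_block(G, chrom, current, "four_gamete"))
                current = [j]
        if len(current) >= 2:
            blocks.append(_make_block(G, chrom, current, "four_gamete"))
    return blocks


def gabriel_blocks(
    G: GenotypeMatrix,
    window_bp: int = DEFAULT_WINDOW_BP,
    ci_low_strong: float = GABRIEL_CI_LOW_STRONG,
    ci_high_strong: float = GABRIEL_CI_HIGH_STRONG,
    ci_high_recomb: float = GABRIEL_CI_HIGH_RECOMB,
    frac_strong: float = GABRIEL_FRAC_STRONG,
) -> list[Block]:
    """Confidence-interval block construction.

    Pairs within ``window_bp`` are classified as strong LD (D' CI lower
    bound >= 0.70 and upper >= 0.98), strong recombination (upper < 0.90),
    or uninformative. A span is a candidate block when its endpoint pair is
    strong LD and >= 95% of its informative inner pairs are strong LD;
    overlapping candidates are resolved longest-span-first, ties leftmost.
    """
    pos = G.snps["pos"].to_numpy()
    blocks: list[Block] = []
    for chrom, lo, hi in _chrom_ranges(G):
        m = hi - lo
        cls = np.zeros((m, m), dtype=int)  # 1 strong, -1 recomb, 0 uninformative
        for a in range(m):
            for b in range(a + 1, m):
                if pos[lo + b] - pos[lo + a] > window_bp:
                    break
                try:
                    ld = pairwise_ld(G, lo + a, lo + b)
                except ValueError:
                    continue
                low, high = ld.dprime_ci
                if low >= ci_low_strong and high >= ci_high_strong:
                    cls[a, b] = 1
                elif high < ci_high_recomb:
                    cls[a, b] = -1
        candidates = []
        for a in range(m):
            for b in range(a + 1, m):
                if pos[lo + b] - pos[lo + a] > window_bp:
                    break
                if cls[a, b] != 1:
                    continue
                sub = cls[a : b + 1, a : b + 1]
                informative = int(np.sum(sub != 0))
                strong = int(np.sum(sub == 1))
                if informative > 0 and strong / informative >= frac_strong:
                    length = pos[lo + b] - pos[lo + a]
                    candidates.append((length, a, b))
        candidates.sort(key=lambda t: (-t[0], t[1]))
        taken = np.zeros(m, dtype=bool)
        chosen = []
        for _, a, b in candidates:
            if not taken[a : b + 1].any():
                taken[a : b + 1] = True
                chosen.append((a, b))
        for a, b in sorted(chosen):
            blocks.append(_make_block(G, chrom, list(range(lo + a, lo + b + 1)), "gabriel"))
    return blocks


def blocks_to_bed(blocks: list[Block], path) -> None:
    """Write blocks as BED-like TSV (0-based half-open file coordinates)."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tn_snps\tmethod\n")
        for b in blocks:
            fh.write(f"{b.chrom}\t{b.start_pos - 1}\t{b.end_pos}\t{b.n_snps}\t{b.method}\n")


def block_containing(blocks: list[Block], snp_index: int) -> Block | None:
    """The block containing a given SNP column index, if any."""
    for b in blocks:
        if snp_index in b.snp_indices:
            return b
    return None
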