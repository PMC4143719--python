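"""Core in-memory containers shared across the pipeline.

Genotypes are stored as minor-allele counts in ``{0, 1, 2}`` with ``-1``
marking a missing call, individuals in rows and SNPs in columns. Haplotypes
within a block are strings over ``{"0", "1"}`` (``1`` = minor allele),
ordered by genomic position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call.
MISSING: int = -1

SNP_COLUMNS = ["id", "chrom", "pos", "minor_allele", "major_allele"]


@dataclass
class GenotypeMatrix:
    """Unphased genotype matrix (individuals x SNPs) with SNP metadata.

    Parameters
    ----------
    values
        ``(n, m)`` integer array of minor-allele counts; ``-1`` = missing.
    snps
        DataFrame with columns ``id, chrom, pos, minor_allele, major_allele``;
        ``pos`` is 1-based and non-decreasing within each chromosome.
    individuals
        Unique individual identifiers, one per row.
    """

    values: np.ndarray
    snps: pd.DataFrame
    individuals: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be 2-D")
        n, m = self.values.shape
        if len(self.individuals) != n:
            raise ValueError(f"{len(self.individuals)} ids for {n} rows")
        if len(self.snps) != m:
            raise ValueError(f"{len(self.snps)} SNP records for {m} columns")
        missing_cols = [c for c in SNP_COLUMNS if c not in self.snps.columns]
        if missing_cols:
            raise ValueError(f"snps table lacks columns {missing_cols}")
        if len(set(self.individuals)) != n:
            raise ValueError("individual ids not unique")
        if self.snps["id"].duplicated().any():
            raise ValueError("SNP ids not unique")
        bad = ~np.isin(self.values, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("genotype values outside {0,1,2,missing}")
        for _, grp in self.snps.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError("positions decrease within a chromosome")
        self.snps = self.snps.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def subset_individuals(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Row subset; ``keep`` is a boolean mask or index array."""
        keep = np.asarray(keep)
        ids = list(np.asarray(self.individuals, dtype=object)[keep])
        return GenotypeMatrix(self.values[keep], self.snps.copy(), ids)

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Column subset; ``keep`` is a boolean mask or index array."""
        keep = np.asarray(keep)
        return GenotypeMatrix(
            self.values[:, keep],
            self.snps.iloc[keep].reset_index(drop=True),
            list(self.individuals),
        )

    def block_values(self, snp_indices: np.ndarray) -> np.ndarray:
        return self.values[:, np.asarray(snp_indices)]


@dataclass
class Block:
    """A haplotype block: a contiguous run of SNP column indices."""

    chrom: str
    snp_indices: np.ndarray  # contiguous, ascending
    start_pos: int
    end_pos: int
    method: str  # "gabriel" | "four_gamete"

    def __post_init__(self) -> None:
        self.snp_indices = np.asarray(self.snp_indices, dtype=int)
        if len(self.snp_indices) < 2:
            raise ValueError("a block needs at least 2 SNPs")
        d = np.diff(self.snp_indices)
        if not np.all(d == 1):
            raise ValueError("block SNP indices must be contiguous ascending")
        if self.end_pos < self.start_pos:
            raise ValueError("end_pos < start_pos")

    @property
    def n_snps(self) -> int:
        return len(self.snp_indices)


@dataclass
class HaplotypeTable:
    """EM-estimated haplotype frequencies for one block."""

    haplotypes: list[str]
    freqs: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    block: Block | None = None

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if len(self.haplotypes) != len(self.freqs):
            raise ValueError("haplotype/frequency length mismatch")
        if len(set(self.haplotypes)) != len(self.haplotypes):
            raise ValueError("duplicate haplotype strings")
        widths = {len(h) for h in self.haplotypes}
        if len(widths) > 1:
            raise ValueError("haplotype strings of unequal length")
        if abs(self.freqs.sum() - 1.0) > 1e-10:
            raise ValueError("frequencies do not sum to 1")

    def frequency(self, hap: str) -> float:
        return float(self.freqs[self.haplotypes.index(hap)])


@dataclass
class DiplotypeDist:
    """Posterior distribution over unordered haplotype pairs for one individual."""

    individual_id: str
    pairs: list[tuple[str, str]]  # (h_m, h_n) with h_m <= h_n lexicographically
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if len(self.pairs) != len(self.probs):
            raise ValueError("pair/probability length mismatch")
        if self.pairs and abs(self.probs.sum() - 1.0) > 1e-10:
            raise ValueError("posterior does not sum to 1")


#: Column label for the pooled rare-haplotype dosage column.
RARE_LABEL = "rare"


@dataclass
class HaploDesign:
    """Expected haplotype dosage design matrix (reference column omitted).

    ``values[i, j]`` is the posterior-expected count (in ``[0, 2]``) of
    haplotype ``columns[j]`` carried by individual ``i``. For an individual
    with a complete genotype the dosages over all haplotypes, including the
    omitted reference, sum to 2.
    """

    individuals: list[str]
    columns: list[str]
    values: np.ndarray
    reference: str
    frequencies: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.individuals), len(self.columns)):
            raise ValueError("design shape mismatch")

    @property
    def n_columns(self) -> int:
        return len(self.columns)
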