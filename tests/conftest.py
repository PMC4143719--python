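import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", deadline=None, derandomize=True)
settings.load_profile("repro")

from haploblock.containers import MISSING, GenotypeMatrix, HaplotypeTable
from haploblock.simulate import SimConfig, simulate_dataset


def make_genotype_matrix(values, chrom="3", pos=None) -> GenotypeMatrix:
    values = np.asarray(values, dtype=np.int8)
    n, m = values.shape
    pos = pos if pos is not None else (np.arange(m) * 1000 + 1)
    snps = pd.DataFrame(
        {
            "id": [f"snp{j}" for j in range(m)],
            "chrom": chrom,
            "pos": pos,
            "minor_allele": "A",
            "major_allele": "G",
        }
    )
    return GenotypeMatrix(values, snps, [f"ind{i}" for i in range(n)])


def diploid_from_pairs(pairs: list[tuple[str, str]]) -> np.ndarray:
    """Genotype rows from explicit (phased) haplotype pairs."""
    return np.array(
        [[int(a) + int(b) for a, b in zip(h1, h2)] for h1, h2 in pairs],
        dtype=np.int8,
    )


@pytest.fixture
def double_het_table() -> HaplotypeTable:
    """Two-SNP table with frequencies {11: 0.4, 10: 0.1, 01: 0.1, 00: 0.4}."""
    return HaplotypeTable(
        haplotypes=["00", "01", "10", "11"],
        freqs=np.array([0.4, 0.1, 0.1, 0.4]),
        loglik=0.0,
        n_iter=0,
        converged=True,
    )


@pytest.fixture(scope="session")
def default_sim():
    """One default-scenario dataset reused by read-only tests."""
    return simulate_dataset(SimConfig(seed=42, n_individuals=300))


def qc_fixture() -> tuple[GenotypeMatrix, dict]:
    """24 x 20 matrix with exactly one planted violation per QC step.

    Row 0 misses 2/20 calls (10% > 5%): removed at the individual step.
    Column 16 has MAF 2/46 after that removal: removed at the MAF step.
    Column 17 misses 2/23 calls among survivors: removed at the SNP step.
    Column 18 is (12 hom-major, 0 het, 11 hom-minor) among survivors,
    an extreme heterozygote deficit with exact HWE p < 1e-6.
    """
    n, m = 24, 20
    base = np.array([0] * 11 + [1] * 11 + [2] * 2, dtype=np.int8)  # MAF 0.3125
    values = np.column_stack([np.roll(base, j) for j in range(m)])
    values[0, 0] = MISSING
    values[0, 1] = MISSING
    # col 16: rare allele on rows 1, 2 only
    values[:, 16] = 0
    values[1, 16] = 1
    values[2, 16] = 1
    # col 17: planted missingness on surviving rows
    values[:, 17] = np.roll(base, 5)
    values[1, 17] = MISSING
    values[2, 17] = MISSING
    # col 18: het deficit (13 zeros, 0 het, 11 twos incl. row 0's zero)
    values[:, 18] = np.array([0] * 13 + [2] * 11, dtype=np.int8)
    expected = {
        "individual_missingness": (1, 0),
        "maf": (0, 1),
        "snp_missingness": (0, 1),
        "hwe": (0, 1),
    }
    return make_genotype_matrix(values), expected
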