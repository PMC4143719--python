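import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import diploid_from_pairs
from haploblock.containers import MISSING, RARE_LABEL, HaplotypeTable
from haploblock.haplotypes import (
    block_design,
    compatible_pairs,
    diplotype_posteriors,
    em_haplotype_frequencies,
    expected_dosage_design,
)
from haploblock.simulate import BlockSpec, simulate_diplotypes
from oracles import eq3_posterior_oracle, two_snp_em_grid_oracle


class TestCompatiblePairs:
    @pytest.mark.parametrize(
        "pattern, n_pairs",
        [
            ((0, 2), 1),  # fully homozygous
            ((1,), 1),  # single het: one unordered pair
            ((1, 1), 2),  # double het: 2^(2-1) pairs
            ((1, 1, 1), 4),
            ((MISSING,), 3),  # missing site: 00, 01, 11
        ],
    )
    def test_pair_counts(self, pattern, n_pairs):
        assert len(compatible_pairs(pattern)) == n_pairs

    def test_pairs_sum_to_genotype(self):
        for a, b in compatible_pairs((1, 0, 2, 1)):
            sums = [int(x) + int(y) for x, y in zip(a, b)]
            assert sums == [1, 0, 2, 1]

    def test_wide_block_raises(self):
        with pytest.raises(ValueError, match="enumerate-infeasible"):
            compatible_pairs(tuple([1] * 26))


class TestEmFrequencies:
    def test_single_snp_equals_allele_counting(self):
        table = em_haplotype_frequencies(np.array([[0], [1], [2]]))
        assert dict(zip(table.haplotypes, table.freqs)) == {"0": 0.5, "1": 0.5}

    def test_all_homozygous_equals_counting(self):
        geno = diploid_from_pairs([("11", "11"), ("00", "00"), ("11", "11"), ("00", "00")])
        table = em_haplotype_frequencies(geno)
        assert dict(zip(table.haplotypes, np.round(table.freqs, 12))) == {
            "00": 0.5,
            "11": 0.5,
        }

    def test_two_snp_matches_grid_oracle(self):
        rng = np.random.default_rng(8)
        spec = BlockSpec(2, ["11", "10", "01", "00"], [0.45, 0.15, 0.1, 0.3])
        dips = simulate_diplotypes(spec, 300, None, 0.0, rng)
        geno = diploid_from_pairs(dips)
        table = em_haplotype_frequencies(geno)
        oracle = two_snp_em_grid_oracle(geno)
        est = dict(zip(table.haplotypes, table.freqs))
        for h in ("11", "10", "01", "00"):
            assert est.get(h, 0.0) == pytest.approx(oracle[h], abs=1e-3)

    def test_four_snp_pool_recovery(self):
        rng = np.random.default_rng(15)
        spec = BlockSpec(
            4, ["1100", "0011", "1010", "0101"], [0.4, 0.4, 0.1, 0.1]
        )
        dips = simulate_diplotypes(spec, 1000, None, 0.0, rng)
        table = em_haplotype_frequencies(diploid_from_pairs(dips))
        est = dict(zip(table.haplotypes, table.freqs))
        for h, f in zip(spec.haplotypes, spec.freqs):
            assert abs(est.get(h, 0.0) - f) < 0.03

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_random_instances_converge_with_valid_frequencies(self, seed):
        """EM is internally checked for monotone log-likelihood; here we
        assert convergence and a proper distribution on random inputs."""
        rng = np.random.default_rng(seed)
        geno = rng.integers(0, 3, size=(rng.integers(2, 30), rng.integers(1, 5)))
        table = em_haplotype_frequencies(geno)
        assert table.converged
        assert table.freqs.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(table.freqs >= 0)

    def test_missing_sites_marginalized(self):
        geno = np.array([[1, MISSING], [2, 2], [0, 0]])
        table = em_haplotype_frequencies(geno)
        assert table.freqs.sum() == pytest.approx(1.0, abs=1e-10)


class TestPosteriors:
    def test_single_het_certain_pair(self):
        geno = np.array([[1]])
        table = em_haplotype_frequencies(np.array([[0], [1], [2]]))
        (d,) = diplotype_posteriors(geno, table)
        assert d.pairs == [("0", "1")]
        assert d.probs[0] == 1.0

    def test_double_heterozygote_worked_value(self, double_het_table):
        """With pool {11: .4, 10: .1, 01: .1, 00: .4}, the cis pair gets
        2*0.16 / (2*0.16 + 2*0.01) = 0.9412."""
        (d,) = diplotype_posteriors(np.array([[1, 1]]), double_het_table)
        post = dict(zip(d.pairs, d.probs))
        assert post[("00", "11")] == pytest.approx(0.9412, abs=5e-5)
        assert post[("01", "10")] == pytest.approx(0.0588, abs=5e-5)
        oracle = eq3_posterior_oracle(
            (1, 1), dict(zip(double_het_table.haplotypes, double_het_table.freqs))
        )
        for pair, p in post.items():
            assert p == pytest.approx(oracle[pair], abs=1e-12)

    def test_full_homozygote_single_pair(self, double_het_table):
        (d,) = diplotype_posteriors(np.array([[2, 2]]), double_het_table)
        assert d.pairs == [("11", "11")] and d.probs[0] == 1.0

    def test_posteriors_sum_to_one_on_simulated_data(self):
        rng = np.random.default_rng(21)
        spec = BlockSpec(3, ["111", "000", "110"], [0.5, 0.3, 0.2])
        geno = diploid_from_pairs(simulate_diplotypes(spec, 100, None, 0.0, rng))
        geno[rng.random(geno.shape) < 0.05] = MISSING
        table = em_haplotype_frequencies(geno)
        for d in diplotype_posteriors(geno, table):
            assert d.probs.sum() == pytest.approx(1.0, abs=1e-10)

    def test_incompatible_individual_falls_back_uniform(self, double_het_table):
        # genotype (2, 0) requires haplotype "10", absent from the table
        table = HaplotypeTable(
            haplotypes=["00", "11"], freqs=np.array([0.5, 0.5]),
            loglik=0.0, n_iter=0, converged=True,
        )
        (d,) = diplotype_posteriors(np.array([[2, 0]]), table)
        assert d.pairs == [("10", "10")] and d.probs[0] == 1.0


class TestDosageDesign:
    def test_unambiguous_homozygote_dosage_two(self, double_het_table):
        dists = diplotype_posteriors(np.array([[2, 2]]), double_het_table)
        design = expected_dosage_design(dists, double_het_table, reference="00")
        assert design.values[0, design.columns.index("11")] == pytest.approx(2.0)

    def test_double_het_dosages(self, double_het_table):
        dists = diplotype_posteriors(np.array([[1, 1]]), double_het_table)
        design = expected_dosage_design(dists, double_het_table, reference="00")
        d = dict(zip(design.columns, design.values[0]))
        assert d["11"] == pytest.approx(0.9412, abs=5e-5)
        assert d["10"] == pytest.approx(0.0588, abs=5e-5)
        assert d["01"] == pytest.approx(0.0588, abs=5e-5)

    def test_row_sums_conserved_at_two(self):
        rng = np.random.default_rng(31)
        spec = BlockSpec(4, ["1111", "0000", "1100", "1110"], [0.3, 0.4, 0.2, 0.1])
        geno = diploid_from_pairs(simulate_diplotypes(spec, 150, None, 0.0, rng))
        table, design = block_design(geno)
        ref_freq = dict(zip(table.haplotypes, table.freqs))[design.reference]
        dists = diplotype_posteriors(geno, table)
        ref_dosage = np.array(
            [
                sum(q * ((a == design.reference) + (b == design.reference))
                    for (a, b), q in zip(d.pairs, d.probs))
                for d in dists
            ]
        )
        totals = design.values.sum(axis=1) + ref_dosage
        np.testing.assert_allclose(totals, 2.0, atol=1e-8)
        assert 0 < ref_freq < 1

    def test_rare_haplotypes_pooled(self):
        table = HaplotypeTable(
            haplotypes=["00", "01", "10", "11"],
            freqs=np.array([0.59, 0.4, 0.006, 0.004]),
            loglik=0.0, n_iter=0, converged=True,
        )
        geno = np.array([[0, 0], [1, 1], [2, 0]])
        dists = diplotype_posteriors(geno, table)
        design = expected_dosage_design(dists, table, pool_below=0.01)
        assert design.columns == ["01", RARE_LABEL]
        assert design.frequencies[RARE_LABEL] == pytest.approx(0.01)

    def test_reference_in_rare_pool_raises(self):
        table = HaplotypeTable(
            haplotypes=["0", "1"], freqs=np.array([0.995, 0.005]),
            loglik=0.0, n_iter=0, converged=True,
        )
        dists = diplotype_posteriors(np.array([[0]]), table)
        with pytest.raises(ValueError, match="rare"):
            expected_dosage_design(dists, table, reference="1")
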