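import numpy as np
import pandas as pd
import pytest

from haploblock.blocktests import (
    bonferroni_threshold,
    haplotype_specific_tests,
    interaction_model,
    omnibus_lrt,
    permutation_test,
)
from haploblock.containers import HaploDesign
from haploblock.haplotypes import block_design, diplotype_posteriors, em_haplotype_frequencies, expected_dosage_design
from haploblock.logistic import RankDeficientError
from haploblock.studies import STUDY_COVARIATES, simulate_block_study


@pytest.fixture
def null_block():
    rng = np.random.default_rng(100)
    geno, cov, _ = simulate_block_study(300, rng, log_or_hap=0.0)
    return geno, cov


@pytest.fixture
def risk_block():
    rng = np.random.default_rng(101)
    geno, cov, _ = simulate_block_study(500, rng, log_or_hap=np.log(3.0))
    return geno, cov


class TestOmnibus:
    def test_zero_haplotype_columns_null_result(self, null_block):
        geno, cov = null_block
        design = HaploDesign(
            individuals=list(cov["individual_id"]),
            columns=[],
            values=np.zeros((len(cov), 0)),
            reference="0000",
        )
        res = omnibus_lrt(design, cov, covariate_cols=STUDY_COVARIATES)
        assert res.lrt_stat == 0.0 and res.p_value == 1.0 and res.df == 0

    def test_df_equals_haplotype_columns(self, null_block):
        geno, cov = null_block
        _, design = block_design(geno)
        res = omnibus_lrt(design, cov, covariate_cols=STUDY_COVARIATES)
        assert res.df == design.n_columns
        assert res.lrt_stat >= 0.0

    def test_detects_risk_haplotype(self, risk_block):
        geno, cov = risk_block
        _, design = block_design(geno)
        res = omnibus_lrt(design, cov, covariate_cols=STUDY_COVARIATES)
        assert res.p_value < 1e-4

    def test_reference_choice_does_not_move_lrt(self, null_block):
        geno, cov = null_block
        table = em_haplotype_frequencies(geno)
        dists = diplotype_posteriors(geno, table)
        stats = []
        for ref in ("0000", "1111"):
            design = expected_dosage_design(dists, table, reference=ref, pool_below=1e-3)
            res = omnibus_lrt(design, cov, covariate_cols=STUDY_COVARIATES)
            stats.append(res.lrt_stat)
        assert stats[0] == pytest.approx(stats[1], abs=1e-6)


class TestHaplotypeSpecific:
    def test_per_block_threshold(self, risk_block):
        geno, cov = risk_block
        _, design = block_design(geno)
        effects, threshold = haplotype_specific_tests(
            design, cov, covariate_cols=STUDY_COVARIATES
        )
        assert threshold == pytest.approx(0.05 / design.n_columns)
        assert len(effects) == design.n_columns
        risk = next(e for e in effects if e.haplotype == "1111")
        assert risk.p_value < threshold
        assert risk.ci95[0] < risk.or_estimate < risk.ci95[1]
        assert 0 < risk.frequency < 1

    def test_two_haplotype_block_reference_swap_reciprocal_or(self):
        rng = np.random.default_rng(7)
        geno = rng.binomial(2, 0.4, size=(400, 1))
        y = (rng.random(400) < 1 / (1 + np.exp(-(-0.5 + 0.6 * geno[:, 0])))).astype(int)
        cov = pd.DataFrame(
            {
                "individual_id": [str(i) for i in range(400)],
                "Y": y,
                "age_ge55": rng.integers(0, 2, 400).astype(float),
            }
        )
        table = em_haplotype_frequencies(geno)
        dists = diplotype_posteriors(geno, table)
        ors = {}
        for ref, col in (("0", "1"), ("1", "0")):
            design = expected_dosage_design(dists, table, reference=ref, pool_below=0.0)
            effects, _ = haplotype_specific_tests(
                design, cov, covariate_cols=["age_ge55"]
            )
            ors[col] = effects[0].or_estimate
        assert ors["1"] == pytest.approx(1.0 / ors["0"], rel=1e-4)


@pytest.mark.parametrize(
    "alpha, n, expected",
    [(0.05, 6389, 0.05 / 6389), (0.05, 1, 0.05), (0.05, 4, 0.0125)],
)
def test_bonferroni_threshold(alpha, n, expected):
    assert bonferroni_threshold(alpha, n) == pytest.approx(expected)


def test_bonferroni_zero_tests_raises():
    with pytest.raises(ValueError):
        bonferroni_threshold(0.05, 0)


class TestPermutation:
    def test_zero_permutations_gives_one(self, null_block):
        geno, cov = null_block
        _, design = block_design(geno)
        assert permutation_test(design, cov, B=0, seed=1,
                                covariate_cols=STUDY_COVARIATES) == 1.0

    def test_strong_effect_attains_minimum_p(self, risk_block):
        geno, cov = risk_block
        _, design = block_design(geno)
        p = permutation_test(design, cov, B=99, seed=2,
                             covariate_cols=STUDY_COVARIATES)
        assert p == pytest.approx(1 / 100)

    def test_agrees_with_asymptotic_p_under_null(self, null_block):
        geno, cov = null_block
        _, design = block_design(geno)
        asym = omnibus_lrt(design, cov, covariate_cols=STUDY_COVARIATES).p_value
        perm = permutation_test(design, cov, B=999, seed=3,
                                covariate_cols=STUDY_COVARIATES)
        assert abs(perm - asym) < 0.05

    def test_seed_required(self, null_block):
        geno, cov = null_block
        _, design = block_design(geno)
        with pytest.raises(ValueError, match="seed"):
            permutation_test(design, cov, B=10, covariate_cols=STUDY_COVARIATES)


class TestInteraction:
    def _interaction_data(self, n, log_or_int, seed):
        rng = np.random.default_rng(seed)
        geno, cov, dosage = simulate_block_study(n, rng, log_or_hap=np.log(2.0))
        age = cov["age_ge55"].to_numpy()
        eta = -0.6 + np.log(2.0) * dosage + np.log(2.0) * age + log_or_int * dosage * age
        cov = cov.copy()
        cov["Y"] = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        return geno, cov

    def test_degenerate_stratum_rank_error(self, null_block):
        geno, cov = null_block
        cov = cov.copy()
        cov["age_ge55"] = 0.0  # nobody in the stratum: interactions all zero
        _, design = block_design(geno)
        with pytest.raises(RankDeficientError):
            interaction_model(design, cov, covariate_cols=STUDY_COVARIATES)

    def test_strong_interaction_detected(self):
        pvals = []
        for seed in range(5):
            geno, cov = self._interaction_data(2000, np.log(3.0), seed)
            _, design = block_design(geno)
            res = interaction_model(design, cov, covariate_cols=STUDY_COVARIATES)
            pvals.append(res.p_value)
        assert np.median(pvals) < 0.01

    def test_type_one_error_controlled(self):
        rng = np.random.default_rng(202)
        n_reject = 0
        n_reps = 400
        for _ in range(n_reps):
            geno, cov, _ = simulate_block_study(500, rng, log_or_hap=np.log(2.0))
            _, design = block_design(geno)
            res = interaction_model(design, cov, covariate_cols=STUDY_COVARIATES)
            n_reject += res.p_value < 0.05
        assert 0.02 <= n_reject / n_reps <= 0.085
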