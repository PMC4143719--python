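# haploblock

Gene-based haplotype association analysis for unphased case-control SNP
data. The package takes raw diploid genotypes (VCF or PED/MAP) and
longitudinal blood-pressure phenotypes, and runs the full chain: outcome
derivation, genotype quality control, ancestry principal components,
a per-SNP logistic scan, haplotype-block construction, EM-based phasing,
and omnibus / haplotype-specific association tests per block. A synthetic
data generator reproduces the statistical structure of such studies so
every stage is testable without access-restricted genotype data.

## The method

For each LD block, haplotype frequencies `p_h` are estimated from the
unphased genotypes by expectation-maximization over the compatible
haplotype pairs of each individual; the posterior probability of an
unordered diplotype `(h_m, h_n)` given genotype `G_i` is

    Pr(h_m, h_n | G_i) = Pr(G_i | h_m, h_n) p_hm p_hn
                         / Σ_{u,v} Pr(G_i | h_u, h_v) p_hu p_hv .

The posterior-expected haplotype dosages enter a logistic model as fixed
covariates (haplotype trend regression / expectation substitution):

    full:     logit P(Y=1) = β0 + β1' X_hap + β2·age≥55 + β3·sex + β4·smoker + β5·PC1
    reduced:  the same model without the haplotype dosage columns X_hap

and the omnibus test is the likelihood-ratio chi-square with df = number of
haplotype columns. When it is significant, per-haplotype Wald tests within
the full model identify the specific haplotype, judged against a per-block
Bonferroni threshold 0.05 / (haplotypes tested). In whole-chromosome mode,
pairwise LD is computed within a 100-kb window, blocks come from the
confidence-interval (Gabriel) or four-gamete algorithm, and the family-wise
threshold is 0.05 / (number of blocks).

The outcome is "ever-hypertension": SBP > 140 mmHg and DBP > 90 mmHg, or
antihypertensive medication, at any of up to four exams. Smoking collapses
to "ever-smoker" and age is dichotomized at 55 years (a restricted cubic
spline basis is provided for checking that choice).

## Worked example

```python
from haploblock.simulate import SimConfig, simulate_dataset
from haploblock.io import write_dataset
from haploblock.pipeline import PipelineConfig, run_pipeline

sim = simulate_dataset(SimConfig(seed=1, n_individuals=400))
paths = write_dataset(sim, "vcf", "demo/data")
report = run_pipeline(PipelineConfig(
    genotypes=str(paths["genotypes"]), exams=str(paths["exams"]),
    subjects=str(paths["subjects"]), outdir="demo/out",
    mode="chromosome", block_method="gabriel", seed=1))
print(report["omnibus"].round(6).to_string(index=False))
```

```
 block_id chrom   start     end  n_snps       lrt  df  p_value  threshold
        0     3 1000000 1003000       4 14.990157   3 0.001825   0.016667
        1     3 1154000 1155000       2  0.584301   1 0.444632   0.016667
        2     3 1306000 1310000       5  5.134590   2 0.076743   0.016667
```

The first block is the simulated causal block: its omnibus LRT (14.99 on
3 df, p = 0.0018) clears the Bonferroni threshold 0.05/3. The
haplotype-specific table then isolates the planted risk haplotype (true
OR 2.72, population frequency 0.3147):

```
haplotype  or_estimate  ci_low  ci_high  p_value  frequency  significant
     1100       1.6027  1.0272   2.5006   0.0377     0.2160        False
     1110       1.3011  0.7616   2.2230   0.3354     0.1135        False
     1111       2.1774  1.4389   3.2950   0.0002     0.3159         True
```

Only the `1111` haplotype survives the per-block threshold 0.05/3; its
estimated frequency (0.316) matches the generating pool. The run log echoes
per-stage counts (QC removals, case/control split, candidate SNPs, blocks).

The same pipeline is available from the shell:

```sh
haploblock simulate --seed 1 --n 400 --out demo/data
haploblock run --config cfg.yaml     # or: qc / pca / scan / blocks / test
```

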