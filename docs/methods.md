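# Methods

This note documents the statistical model, the design choices made where
the design was genuinely open, the synthetic-data generator, and the known
limitations. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Outcome and covariates

An individual is a case ("ever-hypertension") if any of up to four exams
satisfies the blood-pressure criterion or records antihypertensive
medication. The blood-pressure criterion defaults to the conjunction
SBP > 140 mmHg **and** DBP > 90 mmHg (strict inequalities); the more common
clinical disjunction is available via `rule="or"`. Missing exam fields never
satisfy a criterion — a conservative choice that cannot fabricate events —
and an individual whose outcome or smoking status is entirely
undeterminable is dropped with a logged count. Smoking collapses to
"ever-smoker" across exams; age is dichotomized at 55 years. A restricted
cubic spline basis (`rcs_basis`, Harrell parameterization, default knots at
the 5th/50th/95th age percentiles — standard practice for small samples) is
provided to examine the age-outcome shape before committing to the cut.

## Genotype quality control

Filters run in a fixed order, each on the survivors of the previous step:
individual missingness > 0.05, then MAF < 0.1, then SNP missingness > 0.05,
then exact HWE p < 1e-6. Boundary values survive every filter (MAF exactly
0.1 stays, missingness exactly 0.05 stays, HWE p exactly 1e-6 stays). The
HWE test is the exact conditional test (Wigginton-Cutler-Abecasis
recurrence), two-sided by summing the probabilities of all heterozygote
counts no more probable than the observed one, computed on all individuals
rather than controls only. Heterozygosity-rate outliers beyond ±3 sample
SDs (n−1 denominator) are reported but not removed by default. Missing
calls use an internal sentinel distinct from 0/1/2; readers map `./.` (VCF)
and `0 0` (PED) to it.

## Ancestry principal components

EIGENSTRAT-style: each SNP column is centered and scaled by
`sqrt(p(1−p))` with the Bayesian posterior allele frequency
`p = (1 + Σg)/(2 + 2n)`; missing entries are mean-imputed (zero after
centering). Components are eigenvectors of the individual×individual
covariance; the default is a single component, used as the covariate `pc1`
in every association model (`k` is configurable). No Tracy-Widom testing
and no LD pruning before PCA. Sign convention: the largest-magnitude score
of each component is positive, which makes outputs reproducible across
linear-algebra backends.

## Per-SNP scan

Additive dosage coding (0/1/2 copies of the counted allele) — the GWAS
default, consistent with reporting one OR per SNP. Wald odds ratios, 95%
CIs and p-values; individuals missing a SNP are dropped for that SNP only.
Candidate SNPs for the gene-based mode are those with p < 5e-4, with no
genome-wide correction at this stage (they are inputs to the haplotype
analysis, not endpoints).

All logistic models are fit by an in-package IRLS/Newton routine with
step-halving, which guarantees a non-decreasing log-likelihood path and is
checked against statsmodels' MLE in the tests. Convergence requires the
max absolute score below 1e-8 or a relative log-likelihood change below
1e-10. Separation is flagged, not silently reported: a fit is marked
non-converged when any per-SD coefficient magnitude exceeds 30 or the
outcome is fitted perfectly. The flag is scale-aware because PC scores are
unit-norm eigenvector entries (~n^-1/2 scale) whose legitimate coefficients
are numerically large.

## LD and block construction

Two-SNP gamete frequencies come from the same EM used for full blocks
(complete cases for the pair), giving D, D′ and r². The D′ confidence
interval is a likelihood profile on a 101-point D′ grid with allele
frequencies held at their estimates, the multinomial likelihood taken over
the 3×3 unphased genotype table, and 5% of normalized likelihood mass cut
from each tail (the HAPLOVIEW convention, two-sided 90%).

Blocks are built two ways. The confidence-interval (Gabriel) rule
classifies pairs as strong LD (CI lower ≥ 0.70 and upper ≥ 0.98) or strong
recombination (upper < 0.90); a span is a block when its endpoint pair is
strong LD and ≥ 95% of informative inner pairs are strong LD, with
overlaps resolved longest-first and ties leftmost. HAPLOVIEW's special
cases for 2-3-SNP spans are deliberately simplified to these thresholds —
a documented deviation. The four-gamete rule extends a block while every
inner pair shows at most three gametes with EM frequency ≥ 0.01 (the
rule's standard default). Both return non-overlapping, position-sorted
blocks of ≥ 2 SNPs; in chromosome-wide mode pairwise LD is only evaluated
within a 100-kb window. In gene-based (candidate) mode the tested blocks
are those containing scan-significant SNPs; a candidate SNP outside every
block is reported and excluded from haplotype testing.

## Haplotype frequencies, posteriors, design matrix

Within a block, an individual's compatible diplotypes are enumerated by
recursive expansion over heterozygous sites (2^(h−1) unordered pairs for h
het sites); missing sites are marginalized by enlarging the compatible set
rather than dropping the individual. Blocks wider than 25 SNPs are refused
(enumeration infeasible); blocks in this analysis are ≤ 5 SNPs. EM starts
from the product-of-allele-frequency distribution over the candidate set
(floored at 1e-9 to avoid zero-locking), weights heterozygous pairs by 2,
sets each M-step frequency to expected count / 2n, asserts a non-decreasing
observed-data log-likelihood at every iteration, converges when the max
frequency change drops below 1e-8, and prunes frequencies below 1e-12.
Optional restarts from Dirichlet-perturbed starts guard against local
optima; the likelihood is effectively unimodal for the narrow blocks
targeted here, so the default is a single start.

This EM replaces the Bayesian coalescent phasing of external tools such as
PHASE: it is self-contained, exactly reproducible, and uses the same
diplotype-posterior formula; it lacks the coalescent prior, so frequency
estimates on a given dataset will differ somewhat from PHASE's.

The design matrix holds posterior-expected dosages
`Σ_pairs Pr(pair|G_i)·(copies of h)`. The reference haplotype (most
frequent; lexicographic tie-break) is omitted because dosages sum to 2 and
would otherwise be collinear with the intercept. Haplotypes below a 0.01
frequency threshold pool into one `rare` column — chosen for estimate
stability at the ~130-individual scale this package targets; the column is
suppressed when its pooled mass is negligible (< 1e-6), since an
essentially all-zero regressor only destabilizes the fit. Haplotype order
is lexicographic throughout for reproducible columns.

## Omnibus and haplotype-specific tests

The omnibus statistic is 2·(loglik_full − loglik_reduced), clamped at 0,
with df = number of haplotype design columns (the standard nested-LRT df).
Haplotype-specific tests are Wald tests of each column inside the full
joint model — not one-vs-rest refits — against the per-block Bonferroni
threshold 0.05/df. Expected dosages are treated as fixed covariates; the
uncertainty of phase inference is not propagated, the known limitation of
two-stage expectation substitution (it slightly attenuates effects toward
the null). An interaction variant adds haplotype×age columns and tests
them by LRT. A permutation test (B = 999 default, seed mandatory) permutes
the outcome against whole design rows; this breaks covariate and
population structure, so permutation p-values need not match asymptotic
ones — permuting within age strata is offered as partial mitigation.

## Synthetic data generator

The generator emulates exactly what the analysis assumes: haplotype pools
with block-wise LD, diplotypes drawn i.i.d. under HWE within each of two
subpopulations (the second with alternately-shifted, renormalized pool
frequencies, and shifted filler-SNP frequencies, giving PCA a detectable
axis), independent filler SNPs between blocks, a logistic disease model
with haplotype, age, sex, smoking and ancestry effects, and independent
per-SNP/per-individual missingness. Stage sub-streams (labels, diplotypes,
fillers, phenotypes, missingness) are spawned deterministically from one
seed, so the same seed gives byte-identical datasets.

Default scenario: 132 unrelated individuals; one causal 4-SNP block whose
pool {1111: 0.3147, 0000: 0.3853, 1100: 0.18, 1110: 0.12} is
recombination-free (≤ 3 gametes at every pair) and keeps every SNP above
the 0.1 MAF filter; risk haplotype `1111` with OR 2.7215 and age (≥ 55)
OR 2.7489; null 2-SNP and 5-SNP blocks; 5 filler SNPs per gap; sex and
smoking null effects (fractions 0.432 and 0.242); ages uniform on [30, 74)
so 43.2% are ≥ 55; subpopulation fraction 0.2 with a mild 0.05 frequency
shift and ancestry log-OR 0.5; 1% per-SNP and per-individual missingness.
The intercept −0.634 was calibrated analytically, once, so these effect
sizes yield a ~61.4/38.6 case/control split. Exam records are the minimal
longitudinal pattern consistent with the drawn outcome (one hypertensive
exam or a medication flag for cases, none for controls, one smoking exam
for ever-smokers) — the generator validates outcome derivation, not BP
dynamics. Power-limited smoke tests run at the default n; operating
characteristics use n = 200 (2,000 null replicates for type-I error) and
n = 2,000 (100 replicates for effect recovery) — sizes at which the
binomial error of a rejection rate and the SE of a log-OR are small enough
for the asserted tolerances.

What the generator does not emulate: coalescent/recombination-map realism,
family structure, genotyping batch effects, allele-label semantics (minor
vs major letters are assigned arbitrarily), or longitudinal BP dynamics.
Passing tests therefore demonstrate the correctness and calibration of the
statistical machinery under the stated model, not robustness to artifacts
absent from that model.

## Numerical choices and degenerate inputs

- Monomorphic SNPs: error in PCA normalization, pairwise LD and the scan
  (the MAF filter is expected to remove them first).
- A SNP pair's D′ is 0 when Dmax = 0; CI endpoints come from grid search,
  so they are multiples of 0.01.
- An individual compatible with no positive-frequency haplotype pair gets
  a uniform posterior over its enumerated compatible set (logged).
- LRT statistics below −1e-8 raise; small negative values are clamped to 0.
- Permutation p uses the add-one estimator (1 + #{≥ obs})/(B + 1).
- PED/MAP cannot encode which allele genotype values count, so `write_ped`
  emits a `<prefix>.alleles.tsv` sidecar that `read_ped` uses for exact
  round trips; without it the rarer allele is assumed minor
  (alphabetical tie-break).

## Known limitations

- Expectation substitution understates haplotype-effect uncertainty.
- The Gabriel implementation omits HAPLOVIEW's small-span special cases.
- Naive permutation is inconsistent with covariate/population structure
  (documented above); a stratified option only partially addresses it.
- Gene annotation of candidate SNPs and reference-panel merging are out of
  scope; blocks are labelled by coordinates, not gene names.
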