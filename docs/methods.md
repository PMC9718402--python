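# Methods

## Synthetic cohort model

The generator emulates the statistical structure the analysis assumes,
not any particular biobank.

**Genotypes.** Each chromosome carries `snps_per_chrom` biallelic SNPs at
fixed `spacing_bp` intervals, partitioned into blocks of `block_size`
adjacent variants. Per haplotype, a block is a latent Gaussian AR(1)
vector with parameter `rho`; allele 1 is carried when the latent value
falls below the Φ⁻¹(f_j) quantile, with f_j drawn uniformly from
`maf_range`. Dosage is the sum of two independent haplotypes, so each
variant's allele frequency is f_j exactly and within-block dosage
correlation equals the tetrachoric-implied value (checked in the tests by
numeric integration of the bivariate-normal orthant probability). Blocks
and chromosomes are independent — there is no recombination-map realism,
no population structure, and no imputation noise.

**Phenotypes.** A liability-threshold model:

```
L_i = Σ_causal β_j · std(G_ij) + γ_age · std(age_i) + γ_sex · 1[male_i] + ε_i
```

with β_j ~ N(0, h²/n_causal) on standardized dosages, ε ~ N(0, 1 − h²)
(so genetic + noise variance is 1), ages uniform integers on [40, 69] and
sexes Bernoulli(½). The case threshold is the Gaussian quantile of the
liability's theoretical mean and variance at `prevalence_target`, so the
case count is binomial around the target. A `prevalent_fraction` of cases
is flagged prevalent uniformly at random; prevalent cases carry
`incident = 0` and never enter any design. True β are retained so an
oracle PRS can bound what any pipeline can achieve.

**Summary statistics.** An independent cohort of `gwas_n` individuals is
drawn from the *same* variant model (same frequencies, identifiers,
alleles) with fresh random streams; each variant gets a marginal score
test of dosage on case status (β = U/V, se = V^{-1/2}, p from χ²₁).
Monomorphic variants are emitted with β = 0, p = 1. Half the records
report the other allele as the effect allele with the sign flipped, and a
small fraction of variants is rewritten as strand-ambiguous (A/T, C/G;
default 2%) or given a duplicated position (default 0.5%), so the
harmonization path is genuinely exercised.

**Defaults and why.** `n_ind = 8000`, `n_chrom = 22`,
`snps_per_chrom = 500`, `block_size = 20`, `rho = 0.6`,
`maf_range = (0.05, 0.5)`, `spacing_bp = 10⁴`, `h² = 0.3`,
`n_causal = 50`, `prevalence_target = 0.1`, `prevalent_fraction = 0.1`,
`gwas_n = 20000`, `γ_age = 0.15`, `γ_sex = 0.10`. At these values the
default study yields ~720 incident cases, a full 5-controls-per-case
matched training design of roughly 3,000 individuals and an unmatched
testing set of roughly 1,300 — a scale at which the whole pipeline runs
in minutes on one CPU while every stage (including the k-fallback logic)
remains statistically meaningful. The covariate effects are deliberately
small: with large age effects the upper case-age-quintile strata become
so narrow that they cannot supply five controls per case and the design
falls back to k < 5; 0.15/0.10 keeps the headline study at k = 5 while
still shifting case ages measurably (verified by a one-sided test in the
suite).

## Pipeline stages

**QC.** Variants are removed when MAF < 0.001, Hardy–Weinberg χ²₁ p <
10⁻⁵ (no continuity correction; monomorphic ⇒ p = 1), or call rate <
95%, all computed on non-missing dosages of the full cohort before any
sampling. The χ² test is used rather than the exact test: it is
closed-form, deterministic, and indistinguishable at these sample sizes.

**Harmonization.** Matching is by rsid. Precedence per variant:
strand-ambiguous (A/T, C/G) → dropped; duplicated rsid or position on
either side → dropped (all copies); absent from the sumstats → dropped;
otherwise alleles must match directly or after complementing the
non-ambiguous pair, the beta is sign-flipped when the effect allele is
the genotype's a2, and anything else is an allele mismatch. Every input
variant receives exactly one disposition; flipping is an involution
(checked property).

**Matched design.** Age bins are the case-age quintiles (type-7 linear
interpolation; left-closed, right-open except the last; out-of-range ages
clamp to the extreme bins), crossed with sex → 10 strata. k is the
largest value in {5,…,1} every stratum can supply; if even k = 1 fails
somewhere, the k with minimal total shortfall is used and deficient
strata contribute everything they have (logged). Matched sets (case + its
controls) are split 70/30 per stratum, so the training case:control ratio
is exactly 1:k in every stratum under ample controls. The testing set is
the held-out 30% of cases plus 5 unmatched controls per case drawn from
unaffected individuals untouched by training; train/test disjointness is
asserted, and a degenerate all-equal-case-age cohort collapses to
sex-only strata with a warning.

**Grid.** Thresholds: 50 values evenly spaced on −log10 between
0.999·max(−log10 p) and 0.1 (the convention of the bigsnpr C+T
implementation; the endpoints are a convention, not a sensitivity
point).
Clumping processes variants in ascending p (ties: position, then rsid),
removes within `base_kb / r²` kb (center-to-center, inclusive) at squared
correlation > r², computed on mean-imputed training dosages — no external
LD reference. Zero-variance columns correlate 0 with everything and are
never removed by LD. Scoring accumulates per-cell contributions in
ascending-p order so the 50 threshold columns of a cell are prefix sums;
grid storage is float32 by default (float64 on request, used by the
algebraic-identity tests).

**maxCT.** Each of the 1,400 hyperparameter cells is a genome-wide score
(sum of its 22 per-chromosome columns); the training Mann–Whitney AUC
decides, with ties broken to fewer SNPs, then lower r², smaller window,
lower threshold. Constant candidates score exactly 0.5 and can never beat
an informative cell.

**SCT.** L1-penalized logistic regression of case status on the
internally standardized grid columns. The solver is the standard glmnet
coordinate-descent algorithm (IRLS outer loop, soft-threshold coordinate
updates iterated over the ever-active set, sequential strong-rule
screening, warm starts along a descending 30-point log-spaced path from
just above λ_max down to 10⁻² λ_max, path truncation once the active set
exceeds `dfmax = 1000`), written here because generic dense solvers do
not finish a 30,800-column cross-validated path in reasonable time; it is
cross-checked against an independent solver of the same objective
(sklearn saga) to ~10⁻⁸ in the tests. Byte-identical duplicate columns —
the same SNP prefix reached in several (r², window) cells — are fitted
once and mapped back, which changes nothing about predictions. The
penalty is chosen by 10-fold cross-validated deviance, folds stratified
by case status, minimum rule by default; `rule="1se"` (strongest penalty
within one standard error of the minimum) is available and is the
conservative choice under pure noise, where the minimum rule may retain a
few noise columns. Stacking weights α are returned on the original column
scale and collapsed to per-SNP weights `w_j = Σ_g α_g β_j 1[j ∈ S_g]`;
the collapse is an algebraic identity (`X w = S α`), asserted to 10⁻⁸
relative error.

**Evaluation.** AUC is the Mann–Whitney statistic with ties counted ½;
its 95% CI is DeLong's placement-variance estimator (deterministic; a
seeded percentile bootstrap is available behind a flag), truncated to
[0, 1]. OR per SD divides the testing scores by the testing-*control* SD
and exponentiates the univariate logistic coefficient (Wald CI); perfect
separation is reported as a divergence rather than a number. Calibration
probabilities come from a univariate logistic model of training status on
the training PRS applied to the testing scores — the minimal probability
model consistent with evaluating "the PRS alone" — then status is
regressed on logit(p̂); (intercept, slope) = (0, 1) is perfect. Because
both training and testing are ~1:5 case-control samples by design, the
calibration intercept is interpretable within-design only; no re-weighting
to population prevalence is attempted (known limitation). Constant p̂
raises (zero-variance regressor); p̂ at 0/1 is clipped to [10⁻¹², 1−10⁻¹²].

## Randomness and determinism

One global seed fans out through named substreams (variant model, cohort
haplotypes, phenotypes, effects, GWAS cohort, design, CV folds, test
controls), so a change inside one stage never perturbs another stage's
draws, and a fixed seed reproduces every artifact byte for byte.

## What passing tests do and do not show

The generator reproduces block LD, liability-threshold case ascertainment
with covariate confounding, prevalent-case contamination, allele-coding
inconsistencies and effect-size estimation noise — the features the
pipeline's correctness depends on. It does not reproduce realistic LD
decay, minor-allele-frequency spectra, population stratification,
genotyping batch artifacts or imputation dosages; passing tests therefore
certify the *procedures* (matching, clumping equivalence to brute force,
collapse identities, CI coverage, null behavior, oracle dominance), not
real-data effect sizes. Problem sizes in the suite (e.g. 100 null
replicates at 2,000 individuals × 2 chromosomes, 20 signal replicates
with a 20,000-strong GWAS, one full 22-chromosome default run) were
chosen as the smallest scales at which the checked statistics have
standard errors comfortably inside the asserted bands.

## Numerical details

- HWE, MAF and call rate are exact counts; no continuity corrections.
- Clumping tie-breaks (p, then position, then rsid) make retained sets
  permutation-invariant.
- Missing dosages are mean-imputed with *training* means everywhere a
  score is computed.
- The lasso's IRLS weights are floored at 10⁻⁵; the top of the lambda
  path sits a hair (1 + 10⁻⁶) above λ_max so the first model is exactly
  empty rather than numerically at the KKT boundary.
- AUC of an all-constant score is exactly 0.5 by the tie convention.

## Known limitations

- rsid-based matching only (positional matching exists as an option but
  is off by default, mirroring the intersect-on-identifier design).
- No covariate-adjusted models by design: the point of the matched
  design is that age and sex cannot leak into the PRS or its AUC.
- Elastic-net mixing, sign-constrained stacking and external LD reference
  panels are out of scope.
- The calibration intercept is not transportable outside the 1:5
  sampling design (see above).
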