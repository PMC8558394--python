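# Methods

`crpdecomp` implements, end to end, an analysis that decomposes the Black/White
difference in C-reactive protein (CRP) serum levels into genetic-ancestry and
socioenvironmental contributions, together with a synthetic cohort generator
that emulates the data structure of a large UK biobank-style cohort
(n = 433,298; 6,456 Black and 426,842 White participants). Because the real
cohort is access-restricted, the generator's presets transcribe its published
marginals and fitted coefficients as generative ground truth, and the analysis
chain is validated by parameter recovery against that truth.

## Synthetic cohort generator

**Genotypes.** Reference panels follow the Balding–Nichols model: each
variant's ancestral allele frequency p is uniform on (0.05, 0.5) and each
population's frequency is Beta(p(1−F)/F, (1−p)(1−F)/F) with differentiation
F = F_ST = 0.15 (a realistic African–European value). Reference genotypes are
Binomial(2, population frequency); 10,000 independent variants and 200
reference samples per population by default. The Hudson F_ST estimator on the
simulated populations recovers F (tested). No linkage disequilibrium,
phasing, or relatedness is modeled — variants are independent given ancestry —
so LD pruning on these data is a structural no-op and its correctness is
tested on constructed fixtures instead.

**Admixture.** Each participant's ethnic group is drawn from the cohort's
group proportions; the African admixture fraction theta is Normal(group mean,
group SD) **clipped** to [0, 1]. Clipping (rather than rejection sampling) is
a deliberate choice: it reproduces the point masses of fully
European-ancestry and fully African-ancestry participants seen in real
cohorts, and it keeps the Black-group sample mean at ≈ 0.872 for the preset
Normal(0.8781, 0.1050), consistent with the published group mean; rejection
truncation would pull the mean down to ≈ 0.854. Study genotypes are
Binomial(2, theta·f_AFR + (1−theta)·f_EUR).

**Self-identification.** Ethnic identity is generated from ancestry through a
logistic curve: P(identify Black | theta) = logistic(slope·(theta −
crossover)) with preset crossover 0.29 and slope 50. The slope is not
published; 50 puts the 10–90% transition at roughly 0.25–0.33 African
ancestry (within the published 23–44% shift range) and makes self-ID labels
effectively consistent with the group-specific ancestry marginals (mislabel
probability < 1e−6 at the group means). A deterministic threshold mode
(label Black iff theta ≥ crossover) implements the infinite-slope limit for
exact tests.

**Covariates.** Within ethnic group, covariates are drawn independently: age,
BMI, Townsend deprivation index and the two PC proxies are Normal; sex,
smoking and insomnia are categorical; major depressive disorder (MDD) is
Bernoulli; recruitment year is uniform on 2006–2010 (integers). Age, sex and
Townsend marginals per group transcribe the published cohort table
(e.g. White age 56.78 (8.02), Black Townsend 2.63 (3.42)). BMI, smoking,
insomnia and MDD are not published per group; the presets use realistic
biobank-scale values (White BMI 27.4 (4.7), Black 29.6 (5.2); ~10% current
smokers among White participants, 14% among Black; MDD prevalence 0.6–0.8%).
No covariate–covariate correlation is modeled within group, so the
attenuation behaviour of the fully adjusted model arises entirely from
group-differing covariate means.

**CRP.** log CRP = linear predictor + Normal(0, sigma). The linear predictor
applies the configured effects to mean-centered age, mid-span-centered
recruitment year, treatment-coded categoricals (reference: White, female,
never-smoker, never/rarely insomnia) and the Black×male interaction when
configured. Three effect presets exist, because a single linear generator
cannot hold both published coefficient sets simultaneously:

- `ukbb2021-base` — the age- and sex-adjusted model's coefficients as truth
  (ethnicity 0.08, age 0.02/yr, male −0.06), all other effects zero;
- `ukbb2021` — the fully adjusted model's coefficients as truth (BMI 0.22,
  smoking-current 0.84, Townsend 0.04, male −0.46, ethnicity 0.43, ...);
- `ukbb2021-interaction` — base effects plus a Black×male interaction of
  −0.9. The interaction magnitude is not published; −0.9 is the smallest
  round value giving ≥99% power for the likelihood-ratio test at n = 50,000
  with a 1.5% Black fraction (design SE ≈ 0.16), and its sign reproduces the
  published pattern (Black women highest, Black men below White men).

**Marginal calibration.** Every preset solves its intercept and residual SD so
that the White group's marginal CRP is lognormal with mean 2.59 mg/L and
22.58% exceedance of the 3 mg/L clinical threshold. `calibrate_lognormal`
solves the two constraints in closed form (sigma²/2 − c·sigma + ln(t/m) = 0,
c = Φ⁻¹(1−q)); when two positive roots exist the heavy-tailed root is taken
(it matches the direction of the observed CRP SD). The implied White CRP SD
is ≈ 5.2 mg/L versus the observed 4.37 — the real distribution is not
exactly lognormal, and the mean/exceedance pair was prioritized.

**Disease codes.** Per configured phecode, case status is Bernoulli with
logit = baseline + β_CRP·log CRP + β_Eth·[Black] (+ optional age and sex
terms); each case receives one inclusion ICD-10 code of that phecode.
Comorbidity correlation beyond the shared CRP/ethnicity drivers is not
modeled.

**Determinism.** A single seed is fanned out to per-stage streams through
`SeedSequence(seed, spawn_key=(stage_index,))`, so stages can be rerun in
isolation and full runs are bit-reproducible. The covariate/CRP path and the
genotype path draw the admixture truth from the same stage stream, so the
phenotype table and the genotype matrix describe the same participants.

## Ancestry inference

Harmonization intersects datasets on (chromosome, position), corrects
ref/alt swaps by dosage reflection (d → 2−d) and strand flips by
re-complementing, always drops strand-ambiguous (A/T, C/G) variants, and then
applies pooled MAF > 1% and missingness < 5% filters; irreconcilable records
drop the variant with a logged reason rather than aborting. LD pruning is
plink-style: sliding windows of 50 variants advanced by 5; in each correlated
pair (r² > 0.1) the lower-MAF variant is removed (ties drop the later
position). PCA standardizes dosages by the allele-frequency (Patterson)
convention, mean-imputes missing values, and computes the top 10 components
by exact LAPACK SVD up to ~1,000 samples and by seeded randomized SVD above;
the sign convention forces each component's largest-magnitude loading
positive. Joint PCA of study plus reference samples is used (projection-bias
correction is out of scope).

Ancestry fractions solve min‖x − C·w‖², w ≥ 0, where C's columns are
reference-group centroid PC vectors, with fractions w/∑w. One numerical
choice matters here: with exactly two reference groups, PCA centering places
the pooled mean on the African–European centroid line, so the two centroid
vectors are anti-parallel through the origin and the plain NNLS weight ratio
is unidentified — in practice it is resolved by noise in the higher PCs and
can be badly biased. The system is therefore augmented with one constant row
(magnitude = mean centroid norm), a soft affine/sum-to-one constraint that
makes the mixture representation unique; for well-separated many-group
geometries the augmentation is essentially a no-op. All-zero solutions are
flagged and excluded rather than raising. The exclusion filter keeps samples
whose ancestry mass outside {African, European} is ≤ 5% (boundary inclusive,
reading the exclusion rule's ">5%" strictly).

The self-identification curve bins estimated African ancestry into 100
equal-width bins, takes per-bin label frequencies, and smooths the defined
bins by loess (tricube-weighted local linear regression, span 0.75, no
robustifying iterations; the statsmodels `lowess` implementation). The
crossover estimate is the first bin midpoint where the smoothed Black curve
meets the White curve. With span 0.75 the smoothing of a steep sigmoid shifts
the estimated crossing by ~1–1.5 bins (29% → ≈ 30.5%), within the ±2-bin
recovery band; smaller spans remove the shift (threshold-mode identity is
recovered within one bin at span ≤ 0.3). Because the preset cohort mixture
has essentially no participants near 29% African ancestry (White thetas
cluster at ~0, Black at ~0.88), crossover-recovery analyses draw theta
uniformly on [0, 1] — an evaluation design for the identity model and
estimator, not a cohort model.

## CRP models and relative importance

Log (natural) CRP is modeled by OLS and clinically elevated CRP (> 3 mg/L,
strict) by maximum-likelihood logistic regression (Newton, tolerance 1e−8),
through model objects with a statsmodels-style model/results split. Missing
data are handled complete-case per model. Age is mean-centered at the
analysis cohort's mean; recruitment year enters as a continuous covariate.
Perfect separation raises an error that suggests a penalized fallback instead
of silently returning diverged estimates. The likelihood-ratio test requires
nested term sets and identical observations; its statistic is
2·(llf_alt − llf_null) with a chi-square reference. The acute-infection
sensitivity filter removes CRP ≥ 10 mg/L (inclusive).

Relative importance uses the LMG decomposition: each regressor group's
average sequential R² increment over all orderings of entry, computed by the
subset-weighted formula with exact enumeration of all 2^G subsets (G ≤ 20;
the 11-covariate layout needs 2,048 subset regressions via cached
cross-products). Categorical covariates enter as indivisible groups so each
covariate gets one share and one rank (rank 1 = largest; ties share the
smaller rank and the next is skipped). Shares are reported raw and
normalized to the full-model R²; the identity ∑shares = R² holds exactly
and is asserted. The all-orderings brute force lives in the test suite as an
independent oracle.

## PheWAS and the disparity score

A phecode map (CSV: phecode, icd10, exclude_low, exclude_high, category,
description) defines inclusion ICD-10 codes and exclusion phecode ranges per
disease; a 16-phecode toy map across 7 disease categories ships with the
package. Cases carry an inclusion code; controls carry no inclusion code and
no phecode within any exclusion range (the classic example: type 1 diabetics
are removed from type 2 diabetes controls). The scan fits one logistic model
per disease — case status on ethnicity, mean-centered age, sex and log CRP
jointly (a two-separate-models mode is available) — skipping diseases with
fewer than 20 cases and flagging non-convergent or separated fits. Bonferroni
significance is strict p < alpha/m with m defaulting to the number of
diseases actually scanned. The disparity score restricts to diseases
significant in both scans, ranks each effect size ascending (largest effect =
largest rank, average ranks on ties) and sorts by descending rank sum, so
diseases jointly large in both effects rise to the top.

## Validation design, problem sizes and runtimes

The test suite regenerates every input from presets. Headline recovery runs
use the scales at which the analyses are specified: base and fully adjusted
coefficient recovery at n = 50,000 (within 3 SEs of generator truth);
ancestry recovery on a 5,000-participant Black-group cohort with 10,000
variants (mean NNLS African fraction within 1 percentage point of the group's
87.81%); crossover recovery at n = 100,000 (±2 bins); lognormal calibration
at n = 200,000 (±0.3 points of 22.58%). The null calibration of the disease
scan runs 1,000 replicate scans of 50 null diseases at n = 5,000 on a
balanced 50/50 two-group cohort — balance is deliberate: at the preset's 1.5%
Black fraction the expected number of Black cases per disease is ~2, the
ethnicity term quasi-separates, and Wald calibration is not meaningful at
that n. Under the balanced design both scans' type-I error is 5% ± 1.5% and
Bonferroni discoveries stay at the nominal ~0.05 per scan. The full suite
runs in roughly 10 minutes on one CPU; the acceptance script in under a
minute, with the ancestry chain (~40 s) dominating.

## Known limitations

- Variants are independent given ancestry: no LD, so the LD-pruning stage is
  exercised on constructed fixtures, and PCA eigenvalue structure is simpler
  than in real data.
- Covariates are conditionally independent within group; mediation-style
  structure among BMI, deprivation and smoking is not represented, so the
  attenuation of the ethnicity effect in the fully adjusted model reflects
  configured mean differences only.
- The lognormal CRP model cannot match the observed mean, exceedance and SD
  simultaneously; SD is the sacrificed moment.
- Two-group panels only; the six-group global reference structure reduces to
  African/European here because the study cohort excludes >5% other ancestry.
- Passing recovery tests shows the chain inverts its own generator at
  realistic parameter values; it does not certify behaviour on real genotype
  data with LD, batch structure, or diagnosis-code noise.
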