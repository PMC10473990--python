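# Methods

This note records the models, defaults and numerical conventions behind
`quantgwas`, in the spirit of a statistical supplement: what is computed,
under what assumptions, and which choices were genuinely open.

## 1. Synthetic cohort model

The generator produces the data structure the analysis assumes, with a
known ground truth for every downstream stage.

**Demographics.**  Age is truncated-normal (mean 7.2 y, SD 2.3 y) on
[2.2, 14.8] y; sex is Bernoulli(0.5) coded 0 = male / 1 = female; children
are assigned to seven European country strata with weights
(0.07, 0.10, 0.20, 0.15, 0.21, 0.13, 0.14) and to three survey waves with
weights (0.69, 0.22, 0.09).  BMI is linear in age plus Gaussian noise,
`BMI = 14.02 + 0.40·age + N(0, 2.8²)` kg/m², floored at 8 kg/m².

**Genotypes.**  Per SNP, country allele frequencies follow the
Balding–Nichols model: frequency ~ Beta(p(1−F)/F, (1−p)(1−F)/F) around the
base frequency p with divergence parameter F (`fst_like`), clamped to
(0.001, 0.999); within a country, dosages are Hardy–Weinberg
Binomial(2, p_country) draws.  F > 0 yields PCA-detectable stratification;
F = 0 yields exchangeable genotypes for null calibration.

**Phenotype (location–scale).**  With dosages g_j,

    log I = a0 + a1·age + a2·age² + a3·sex + a4·BMI + c(country)
            + Σ_j β_j g_j + (1 + Σ_j γ_j g_j) · σ · ε,    ε ~ N(0,1).

A location SNP (β ≠ 0, γ = 0) shifts all conditional quantiles equally; a
scale SNP (γ ≠ 0) multiplies the residual SD per allele, so the conditional
τ-quantile slope is the closed form **β + γσΦ⁻¹(τ)** — the ground truth the
test-suite checks fitted paths and heteroscedasticity tests against.  The
generator rejects configurations for which the scale multiplier
1 + Σ_j γ_j g_j could reach ≤ 0 at an attainable genotype.

**Default calibration.**  Defaults were derived once, by moment matching
against the marginal structure of the cohort this analysis was designed
for: insulin ≈ log-normal with mean 35 pmol/l and SD ≈ 30 pmol/l (hence
total SD of log-insulin ≈ 0.74 and mean ≈ 3.28), corr(log I, age) ≈ 0.38
and corr(log I, BMI) ≈ 0.54.  Solving the implied moment equations gives
a1 = 0.075, a4 = 0.118, σ = 0.60, a0 = 0.764; a2 = 0 and a3 = −0.02 by
default (age² and sex effects are small at this resolution); country
offsets are N(0, 0.05²).  These are definitions of the simulation's study
conditions, not fitted quantities; simulated cohorts reproduce the target
correlations to within ±0.05 and are strongly right-skewed.

The bundled two-SNP scenario used by the end-to-end checks sets
γσ = 0.12 per allele (γ = 0.2 at σ = 0.6) at EAF 0.3 for the scale SNP and
β = 0.08 for the location SNP at n = 3000.  At these settings the
heteroscedasticity test has essentially full power (observed p ≤ 1e−9
across seeds), while the probability that the scale SNP also clears the
*suggestive* logistic-scan tier (10⁻⁵) in a tail scan is roughly one third
to one half per cohort — the scan dichotomises and therefore discards
information that the quantile process uses.  The bundled scenario is a
fixed-seed fixture; across fresh seeds the hit-list membership is the
stochastic element, not the heteroscedasticity verdict.

**What the generator does not emulate:** linkage disequilibrium between
SNPs (draws are independent given country), longitudinal repeat
measurements, assay error, pubertal hormone dynamics, and sex-specific
genetic effects.  Passing tests on this generator therefore demonstrate
the estimators' statistical behaviour under the assumed location-scale
mechanism, not robustness to LD structure or measurement artefacts.

## 2. Percentile-rank scoring

Scoring strata are sex × age bins (default width 1.0 y) over the reference
sample's age range; a stratum under 30 values is merged with an adjacent
bin of the same sex (the smaller neighbour, ties to the left) until all
strata are large enough.  The percentile rank of insulin value x in a
stratum with sorted values v₁…v_n is the linearly interpolated mid-ECDF
position ((i − 0.5)/n at v_i), in percent, clamped to
[100·0.5/n, 100·(n−0.5)/n] so that z = Φ⁻¹(rank/100) is always finite.
Children whose age falls outside their sex's covered range are scored
against the nearest bin and flagged.  The reference sample is a separate,
user-suppliable input (scoring against an external lean reference shifts
mean ranks above 50); it defaults to the analysis sample itself, in which
case mean rank ≈ 50 and z ≈ N(0,1) by construction.

Longitudinal tables are reduced to one record per child before scoring:
the *valid* record at the youngest age, where validity means fasted ≥ 8 h,
no diabetes diagnosis, no glucose-lowering medication (flag columns, each
optional); children with no valid record are excluded and logged.

An empirical ECDF reference was chosen over GAMLSS/LMS-type smoothed
percentile curves: it is assumption-free, exactly invertible in tests via
the probability integral transform, and adequate at the stratum sizes the
pipeline requires.  The published smoothed reference curves it replaces
are not embedded.  Raw BMI (not the BMI z score) is the default adiposity
covariate downstream, matching the original analysis; a BMI-z route exists
as an option.

## 3. Logistic percentile scans

Case rules: P15/P25 — case iff rank ≤ threshold; P50/P75/P85 — case iff
rank ≥ threshold; the complement is the control group.  Covariates:
intercept, age, age², sex, BMI, survey and country indicators (reference
categories dropped), and the top K principal components of the
mean-imputed, variance-standardised dosage matrix (constant SNPs
excluded).  K defaults to 32 but is capped at n/50 for small cohorts
(logged); age² and survey indicators are individually toggleable.

Each SNP enters as minor-allele dosage (flipped and EAF recomputed if raw
frequency > 0.5).  Fitting is maximum likelihood by IRLS, converged when
max |score| < 1e−8 or the relative deviance change is < 1e−10 (≤ 50
iterations), warm-started per SNP from the covariates-only fit; covariance
is the inverse observed information and p values are two-sided Wald.
Quasi-complete separation is flagged via collapsed fitted probabilities
with extreme coefficients; the record is kept with `converged=False`.
Missing dosages are handled complete-case per SNP (mean imputation is used
only inside the PCA).  Tiers: genome-wide p < 5×10⁻⁸, suggestive
p < 10⁻⁵.  Genomic-control λ (median χ² over its null median) is exposed
as the calibration diagnostic.

## 4. Quantile-regression process

**Estimation.**  β̂(τ) minimises Σ ρ_τ(y − x′β) with
ρ_τ(u) = u(τ − 1{u<0}).  The problem is solved exactly as a linear
program.  For speed the *dual* LP (maximise y′a subject to
X′a = (1−τ)X′1, 0 ≤ a ≤ 1) is solved with HiGHS; the primal vertex is
recovered from the interior dual variables (complementary slackness: an
interior a_i forces residual zero) and verified through the duality gap at
relative tolerance 1e−7, falling back to the primal LP on degeneracy.
Tie-break: the returned solution is an LP vertex; for an intercept-only
design this is the lower endpoint of the minimising interval, i.e. the
type-1 empirical quantile.  The engine is validated against exhaustive
enumeration of all p-subsets of interpolated observations on small
problems (every vertex of the feasible polytope interpolates p points).

**Sparsity.**  s(τ) = 1/f(F⁻¹(τ)) is estimated by the Siddiqui difference
quotient [Q̂(τ+h) − Q̂(τ−h)]/(2h) on the empirical quantile function of the
fit's residuals, with the Hall–Sheather bandwidth at nominal level 0.05,
clamped so 0 < τ−h < τ+h < 1 (flagged when clamped, error when the clamp
collapses); estimates are floored at 1e−6 with a warning.  The ~p basic
residuals — exact zeros of the LP fit — are excluded from the quantile
function first, as the classical implementations do; keeping them
compresses the central residual spacings and biases s downward in finite
samples.

**Inference.**  Under iid errors,
Var(β̂_g(τ)) = τ(1−τ) s(τ)² [(X′X)⁻¹]_gg, and across levels
Cov(β̂_g(τᵢ), β̂_g(τⱼ)) = (min(τᵢ,τⱼ) − τᵢτⱼ) s(τᵢ)s(τⱼ) [(X′X)⁻¹]_gg —
the Brownian-bridge structure of the quantile process.  This iid "sparsity
method" is the default; a Hendricks–Koenker (nid) sandwich and an
individual-resampling bootstrap of the whole path are available as
alternatives (`se_method="nid"` / `"bootstrap"`).

**Heteroscedasticity Wald test.**  The flatness contrast takes the 18
consecutive differences D of the 19-level path; W = (Db)′(DΣD′)⁺(Db) with
degrees of freedom rank(DΣD′) (pseudo-inverse, relative tolerance 1e−10)
and an upper-tail χ² p value.  Consecutive differences were preferred to
deviation-from-mean contrasts because they are invariant to the path's
parameterisation and well-conditioned under the near-singular process
covariance.  Measured over 1000-replicate null simulations (pure location
SNP, n = 1000), the empirical size at nominal 0.05 is ≈ 0.04–0.06
depending on the seed stream — consistent with nominal at this n, with
mild residual sensitivity to the sparsity estimates entering the
covariance.

**Goodness of fit.**  Koenker–Machado R¹ = 1 − V_full/V_restricted on
minimised check losses of nested fits, with the df-adjusted variant
1 − (V_full/(n−p_full))/(V_restricted/(n−p_rest)), floored at 0 (flagged).
The exact df correction of the original SAS macro is not published; the
ratio above is this package's convention.  ΔR¹_adj profiles compare
base+SNP-set against base, both referred to the intercept-only fit, per τ.

**Companion linear effect.**  OLS of log-insulin on dosage plus the same
covariates; classical SEs, t-based p (n−p df).

**Multiple testing.**  Bonferroni at the reporting level α/m where m is
the number of profiled SNPs (covering the paired heteroscedasticity and
linear tests as one family per SNP, matching the original accounting, e.g.
0.05/25 = 0.002 for 25 SNPs); m is derived from the run, never hard-coded.

## 5. Genetics utilities

**APOE-ε4 counting.**  Haplotypes on (rs429358, rs7412): ε2 = (T,T),
ε3 = (T,C), ε4 = (C,C); ε1 = (C,T) is treated as absent, so the ε4 count
equals the rs429358 C-allele count.  The double heterozygote is
phase-ambiguous between ε2/ε4 and ε1/ε3 and resolves to ε2/ε4 (count 1,
flagged) by the population-frequency argument; genotype pairs that would
force an ε1 are likewise flagged.

**Two-locus LD.**  Haplotype frequencies from unphased dosages by EM over
the double-heterozygote ambiguity (tolerance 1e−10, ≤ 1000 iterations);
D = p_AB − p_A p_B, D′ = |D|/D_max, r² = D²/(p_A p_a p_B p_b).

**Units.**  Insulin mIU/l → pmol/l via the factor 6.945; rounding only at
presentation (65 mIU/l prints as 451 pmol/l).

## 6. Pipeline and determinism

`run_pipeline` executes: first-valid-observation selection → reference fit
and scoring → genotype PCA → the five scans → hit selection (suggestive or
better in any scan) → quantile process + heteroscedasticity + linear tests
per hit at the run-derived Bonferroni level → per-outcome ΔR¹ profiles →
TSV tables, a Manhattan export per outcome, and a JSON report embedding a
config fingerprint (SHA-256) and the seed.  All randomness flows from one
master seed through `numpy.random.SeedSequence` spawns; reruns with the
same config are byte-identical.  An empty hit list skips the process stage
and is noted in the report.

## 7. Problem sizes used by the checks

The automated checks run, per invocation: the engine-vs-oracle comparison
on 200 instances with n ≤ 12, p ≤ 2; sparsity calibration at n = 5000;
type-I error of the Wald test over 1000 replicates at n = 1000; tail-power
medians over 50 cohorts at n = 3000; one bundled end-to-end run with 502
SNPs at n = 3000; a 1000-SNP null scan at n = 1000; and scorer calibration
at n = 2000.  These sizes were chosen as the smallest at which the
asymptotic approximations under test are expected to hold cleanly.

## 8. Known limitations

- The iid sparsity covariance is an asymptotic approximation; at moderate
  n the Wald test's size fluctuates around nominal by roughly ±0.01
  (measured at n = 1000); the bootstrap route is the cross-check.
- The empirical reference scorer does not smooth across age bins, so rank
  estimates near bin edges are slightly noisier than GAMLSS-type curves.
- PCA is computed without LD pruning (the generator produces LD-free
  SNPs); pruning would be advisable on real array data.
- VCF input reads GT only (no dosage/GP fields); multi-allelic sites are
  skipped.
- X-chromosome models, imputation, meta-analysis and censored/IV quantile
  regression are out of scope.
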