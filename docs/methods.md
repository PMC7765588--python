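# Methods

This note documents the statistical procedures implemented in `epmed`, the
assumptions behind them, the design choices made where several reasonable
conventions exist, and what the synthetic-data experiments do and do not
demonstrate.

## 1. Genotype handling

Markers are biallelic; the minor allele is designated from observed
frequencies at read time (ties broken lexicographically and logged). The
minor-allele frequency is

    MAF = (2·n_hom-minor + n_het) / (2·n_called),

with missing calls removed from the denominator, and is computed on the
*unrelated* subjects (probands + controls) to avoid inflation by family
structure.

**Coding rule.** A marker enters the model as a single numeric predictor:
additive minor-allele dosage 0/1/2 when MAF ≥ 0.35 (the threshold is
inclusive), otherwise presence/absence of the minor allele (0/1). The
additive model is a linear dose effect by construction; a two-dummy
parameterization is deliberately not the default (it would change the
model's degrees of freedom), though the coding table records every
decision so a sensitivity analysis can recode.

**Hardy-Weinberg equilibrium.** The default test is the 1-df χ² comparing
observed genotype counts with p², 2pq, q² expectations at the estimated
allele frequency; monomorphic markers return p = 1 with a warning (the
test is undefined). An exact conditional test (enumeration of heterozygote
counts given allele counts) is available behind a flag for small samples.
QC reports flag HWE p-values against per-gene Bonferroni thresholds,
0.05 divided by the number of markers in the gene (3 for DYX1C1 and DCDC2,
4 for KIAA0319 and ROBO1, 6 for GRIN2B).

**Missing data.** Missing genotypes are excluded per-marker for
frequencies and HWE; at model time, subjects with any missing model
variable are listwise-dropped with a logged count. This is the simplest
defensible convention; no imputation is attempted.

## 2. Endophenotype scoring

* **Temporal order judgment (RAP).** Per-ISI accuracy (%) over 8 trials at
  ISIs 20/40/80/120/280 ms; per ISI the sample 25th/75th percentiles
  (linear interpolation between order statistics — the common default;
  no particular estimator is canonical here) define codes 1 (≤ P25),
  3 (≥ P75), else 2. Rule order resolves degenerate distributions
  (P25 = P75 → everyone codes 1, with a warning). The subject's RAP score
  is the *mean* of the five ISI codes; the per-ISI coding itself does not
  dictate an aggregate, and the mean is the natural single score.
* **Rapid naming (RAN_rt).** Mean vocal RT over correct trials, excluding
  RTs > 1000 ms as outliers, then z-normalized within the sample ("plain"
  z-score with the sample SD) to avoid scaling effects in the mediation
  model.
* **Warning effect (WE).** RTs outside [150, 1500] ms are excluded
  (boundaries inclusive on the keep side); per SOA (100, 250 ms) the
  composite is the mean of the four modality × validity cell means, and
  WE = composite(250) − composite(100) in ms. Any empty cell after
  filtering yields a missing WE.
* **Motion illusion (RTLI).** Per-subject proportions of perceived
  rotation at 11 contrast levels (0–10%) are fitted by least squares to
  the logistic y = 1/(1+exp(−b(x−t))) with bounds 0 and 1, b > 0 free
  slope and t the 50% threshold (y(t) = 0.5 identically). A coarse
  (b, t) grid pre-screen followed by local refinement from the best three
  starts guards against local minima; flat response curves are flagged
  non-converged with missing parameters. For modelling, b is
  log-transformed and t square-root-transformed (normality transforms);
  non-positive slopes become missing.
* **Reading composite.** Each of six reading measures (text, word and
  pseudo-word speed and errors) is z-scored within the sample, error
  counts sign-flipped so higher = better, and the composite is the mean of
  available z-scores. Within-sample z-scores stand in for grade norms,
  which are not distributable.
* **Correlation screen.** Two-tailed Pearson correlations on
  pairwise-complete observations between coded markers, endophenotypes and
  reading, as a descriptive pre-model screen.

Age is *not* partialled out during scoring; it travels with the scored
table and enters the path model as a covariate on RTLI_b, RAP and RAN_rt.

## 3. Path model and bootstrap

The model is recursive with observed variables only: each mediator on all
coded markers (plus age where declared), the outcome on all markers and
mediators; five mediator residual covariances are freed (WE–RTLI_b,
RAP–RTLI_b, RAP–RTLI_t, RAP–RAN_rt, RTLI_b–RTLI_t); the exogenous
(marker + age) covariance block is unconstrained. All variables are
centered and scaled to unit SD before fitting, so coefficients are
standardized; scale constants are recorded for exact back-transformation.

**Estimation.** Equation-wise least squares. For a recursive system whose
freed residual covariances do not involve regressors of the same equation,
the equation-wise solution coincides with the maximum-likelihood point
estimates, and it is orders of magnitude cheaper inside the bootstrap loop
than iterative ML. Residual variances/covariances come from equation
residuals. Rank-deficient designs raise an error naming the collinear
columns.

**Effect decomposition.** specificⱼₖ = aⱼₖ·bⱼ, totalₖ = Σⱼ specificⱼₖ
(the additivity identity holds to machine precision by construction),
total effectₖ = c′ₖ + totalₖ.

**Cluster bootstrap.** Families are the sampling units (relatedness is the
clustering variable; unrelated controls are singleton clusters). Each
replicate resamples clusters with replacement to the original cluster
count, keeping family composition intact, then re-standardizes and refits
— standardization is part of the estimator, so it is recomputed per
replicate. Replicates in which a coded marker becomes constant or the
normal equations are singular are dropped and counted as failures
(> 5% warns, > 25% aborts). Intervals are bias-corrected (BC, not BCa —
no acceleration term): z₀ = Φ⁻¹(share of replicates below the point
estimate, clipped to (1/(B+1), B/(B+1))), bounds at the Φ(2z₀ ± z_{α/2})
percentiles of the replicate distribution. An effect is significant when
its CI excludes zero. Default B = 5000.

**Calibration behaviour worth knowing.** With *both* paths of a product
truly zero, the sampling distribution of a·b is sharply peaked at zero and
percentile-type intervals are strongly conservative: in our simulations
(500 null cohorts × 500 replicates) the 95% BC CI excluded zero in ≈ 0.4%
of datasets, not 5%. This is a well-documented property of
product-of-coefficients bootstrap tests, not an implementation artifact:
with only one path null (a = 0, b = 0.298) the measured rejection rate is
≈ 8%, and coverage of a nonzero specific indirect at study scale is ≈ 96%
for nominal 95% intervals.

## 4. Fit indices and power

The model-implied covariance Σ(θ) is assembled as (I−B)⁻¹Ψ(I−B)⁻ᵀ from the
fitted coefficients, residual (co)variances and the free exogenous block.
With S the sample covariance of the v = p + 7 observed variables,

    F_ML = ln|Σ| − ln|S| + tr(SΣ⁻¹) − v,   χ² = (n−1)·F_ML,
    RMSEA = sqrt(max(χ²−df, 0) / (df·(n−1))),
    CFI   = 1 − max(χ²−df, 0) / max(χ²_B−df_B, χ²−df, 0),
    SRMR  = rms of standardized residual covariances (diagonal included;
            a no-diagonal variant is flag-selectable since dialects differ).

The RMSEA 90% CI inverts the noncentral χ² (n−1 convention). The CFI
baseline is the independence model with free variances (the universal
convention). The default model's own counting gives df = 8: of the v(v+1)/2
moments, the free parameters leave exactly the 5 omitted mediator residual
covariances, the 2 omitted age→mediator paths and the omitted age→outcome
path as constraints. `ModelSpec(covariate_on_outcome=True)` frees the
latter; fit and power functions take df as an explicit input throughout.

**RMSEA power.** λ(ε) = (n−1)·df·ε²; the critical value is the upper-α
quantile of the noncentral χ²(df, λ(ε₀)) and power is the upper tail under
λ(εₐ). The default null is exact fit (ε₀ = 0); at df = 8, n = 302,
εₐ = 0.087 this yields power ≈ 0.883, whereas the close-fit null
(ε₀ = 0.05) yields less — only the exact-fit convention is consistent with
a reported power above 80% at these design values, so it is the default
and ε₀ stays exposed.

**Joint-significance mediation power.** With standardized paths a, b, c′:

    SE(a) = sqrt((1−a²)/(n−2)),
    R²_Y  = b² + c′² + 2abc′,
    SE(b) = sqrt((1−R²_Y)/((n−3)(1−a²))),
    power = Φ(|a|/SE(a) − z_{1−α/2}) · Φ(|b|/SE(b) − z_{1−α/2}),

the probability that both path tests reject — the standard calculator
approach for indirect-effect power. A Monte-Carlo mode (simulating the
standardized single-mediator system and running both t-tests) is provided
for verification; analytic and simulated power agree within ±2% in the
test suite. Note the formula treats each tail one-sidedly after taking
|·|: at a = 0 the a-factor is Φ(−z_{1−α/2}) = α/2, so the power of a
truly-null pathway is α/2 times the b-test power, below the α bound.

## 5. Synthetic cohort generator

The generator is the test bed for everything above, with the study's
structure as defaults:

* **Sample.** 99 nuclear families, each a proband plus 1–2 additional
  siblings (uniform; the real sibling-count distribution is unreported),
  and 79 unrelated controls in singleton families — ≈ 320 subjects.
* **Genotypes.** 20 markers across DYX1C1, DCDC2 (including the READ1
  presence/absence microdeletion), KIAA0319, ROBO1 and GRIN2B, with the
  published unrelated-subject MAFs as defaults. Two parental genotypes per
  family are drawn from HWE proportions and transmitted Mendelianly, so
  sibling genotype correlation is genetically real rather than imposed;
  controls are independent HWE draws. Markers are mutually independent
  (no linkage-disequilibrium blocks are simulated).
* **Structural equations.** Coded genotypes are standardized by their
  theoretical moments; mediators and outcome are built on the unit-variance
  scale so the configured A (5×20 gene→mediator), B (mediator→reading),
  Cp (direct) and age→mediator paths are the true standardized effects.
  Defaults place the headline pathway on ROBO1-rs9853895
  (a = −0.188 → RAP, −0.249 → RTLI_b; b = 0.298, 0.249; c′ = −0.111) and
  zero elsewhere. Age is uniform over 7–14 years (school age; the true age
  distribution is unreported) with moderate standardized age paths
  (+0.25 on RTLI_b and RAP, −0.25 on RAN_rt). Residuals are Gaussian
  (matching the linear-Gaussian model) with ±0.2 correlations on the five
  controlled mediator pairs (signed by trait polarity) and a within-family
  ICC of 0.2 on mediator and outcome residuals (no familial residual
  correlation is quantified anywhere; 0.2 is a moderate familiality
  default). Configurations whose paths imply negative residual variance
  are rejected at construction, naming the offending equation.
* **Trial emission.** Optionally the generator inverts the scoring rules:
  per-ISI Bernoulli accuracies increasing in latent RAP skill (probit
  link, chance floor 50%); 32 Gaussian naming RTs around 450 + 60·z ms;
  cued-detection RTs with a −20 + 15·z ms SOA-250 shift per subject
  (32 valid + 32 invalid + 16 catch trials per modality); binomial illusion
  responses from a logistic whose log-slope and root-threshold are linear
  in the latent scores; and six reading indicators loading √0.548 on the
  latent composite so their pairwise correlation is 0.548. A noiseless
  RTLI mode emits expected per-level counts (continuous, not
  integer-rounded) so the psychometric fit inverts the logistic exactly; a
  trial-count multiplier supports precision studies. At 10× trial counts
  the scored values correlate > 0.9 with the latent truth for all five
  mediators and the composite.

**What the synthetic experiments show — and don't.** They demonstrate
internal correctness: parameter recovery, CI coverage (≈ 96% at study
scale), determinism under seeding, and exact effect-decomposition
identities. They do not emulate linkage disequilibrium, genotyping error,
assortative mating, non-Gaussian or heteroscedastic task noise, floor and
ceiling effects in real tasks, or informative missingness — so passing
tests certify the estimator, not the robustness of any substantive
finding to those real-data features.

## 6. Numerical choices and problem sizes

Bootstrap replicates are solved by Cholesky-factorized normal equations on
standardized arrays (a rank-deficient factorization marks the replicate
failed); full-sample fits additionally check rank via SVD. The simulation
suites use 500 null datasets × 500 replicates (type-I calibration) and
200 datasets × 500 replicates (coverage), sizes at which the binomial
uncertainty of the measured rates is ≈ ±1–2 percentage points; production
analyses should keep the 5000-replicate default. Psychometric fits use
tolerances of 1e-14 so noiseless round trips recover parameters to at
least four decimals. Seeds flow through `numpy.random.default_rng`
everywhere; identical configuration + seed reproduces cohorts, fits and
intervals byte-for-byte.

## 7. Known limitations

* Clustering is handled by the cluster bootstrap only; no robust (sandwich)
  standard errors or survey-style ML corrections are offered.
* No latent-variable measurement models, moderated mediation, haplotype
  phasing or genotype imputation.
* The BC interval's complete-null conservativeness for products (see §3)
  means "no significant mediation" under a true complete null is far more
  frequent than 95% — a feature of the method class, inherited knowingly.
* The detection-task contrast threshold measured alongside the illusion
  task is carried through but never used downstream.
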