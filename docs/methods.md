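# Methods

This note records the models implemented by `spiroprm`, the choices made
where the design was genuinely open, and what the synthetic data can and
cannot establish.

## Reference spirometry

Predicted values and lower limits of normal (LLN) come from the NHANES
III adult reference equations (Hankinson, Odencrantz & Fedan 1999):
`value = b0 + b1·age + b2·age² + b3·height²`, stratified by sex and
race/ethnicity (Caucasian, African-American, Mexican-American), with the
FEV1/FVC equations linear in age and returned as a dimensionless
fraction.  The LLN shares the age terms and carries its own intercept
and height² coefficient.  Two caveats:

* For FEF25–75 the package approximates the LLN as
  `predicted − 1.645·RSD` with per-stratum residual standard deviations
  chosen from typical adult values (0.58–0.78 L/s); the analysis
  pipeline itself uses only percent-predicted FEF25–75, never its LLN.
* Coefficients were transcribed from the published adult tables and
  cross-check internally (FEV1 and FVC predictions reproduce the direct
  ratio equations to ≈0.01 at age 60); users needing regulatory-grade
  values for every stratum should verify against the original tables.
  Unknown race categories fall back to the Caucasian set with a logged
  warning (deterministic, matching common clinical software); the
  fallback can be disabled.

"Normal FEV1" is not standardized; the default rule is
post-bronchodilator FEV1 ≥ LLN(FEV1), consistent with the use of LLN
elsewhere in the analysis, with `normal_fev1_rule="pct80"` (≥ 80%
predicted) as a switch.  Membership in the unobstructed groups
additionally requires FEV1/FVC ≥ LLN so that young subjects with
0.70 < ratio < LLN are not counted as unobstructed (configurable).
Boundary ties (ratio exactly 0.70 or exactly the LLN) follow the strict
inequalities of the group definitions and are logged.  The below-LLN
comparison group ("the least-obstructed quartile of subjects under
their LLN") is ambiguous between ratios strictly above the stratum's
75th percentile and at-or-above that cutpoint; both readings are
implemented (`group4_mode="top_quartile" | "cutpoint"`).

Annual FEV1 change is the per-subject OLS slope of FEV1 (ml) on time
(years = days/365.25) across all visits, requiring at least two
post-bronchodilator measurements spanning ≥ 200 days; subjects failing
the precondition are excluded with a logged reason.

## Parametric response mapping

Voxels inside the lung mask are classified by joint thresholds on the
co-registered pair: emphysema iff inspiratory HU < −950; fSAD iff
inspiratory HU > −950 and expiratory HU < −856; normal iff inspiratory
HU > −950 and expiratory HU ≥ −856.  The inequalities are strict on
both sides, so a voxel at exactly −950 HU on inspiration (a real case
with integer HU) is reported separately as *unclassified*; a switch
folds it into normal.  Choices the source conventions leave open:

* Percent denominators use all masked voxels (whole-lung), the
  PRM-literature convention; exclusion of airways/vessels is not
  modelled.
* The emphysema rule deliberately omits an expiratory condition
  (classic PRM adds expiration < −856), following the literal
  definition used in the borderline-obstruction analysis.
* Registration of expiration to inspiration is assumed done upstream;
  `classify_prm_voxels` exposes an `align` hook defaulting to identity.

Pi10 is obtained by regressing √(wall area) on internal perimeter
across measured airways (OLS) and evaluating the fit at 10 mm; a single
airway is accepted only if measured exactly at 10 mm.

## Normative upper limits of normal

The ULN of a PRM metric is its conditional 95th percentile among
healthy never-smokers, modelled as a main-effects linear function of
age, sex, BMI and scanner (one-hot against a reference scanner; no
interactions or transformations, since none are specified).  The fit
minimizes the pinball loss via the standard quantile-regression linear
program, solved with a deterministic solver (HiGHS through
scipy), so results are exactly reproducible; the fitter verifies the
optimality sign conditions `#(y < Xβ̂) ≤ τn` and `#(y > Xβ̂) ≤ (1−τ)n`.
For an intercept-only design the minimizer is an order-statistic
interval and the lower endpoint is reported.  Predictions are floored
at 0 (a percentage cannot be negative); presence is the strict
comparison `observed > ULN`; τ defaults to 0.95 and is a parameter.
Scanners unseen at fit time raise an error unless a reference-scanner
fallback is requested.

In the full pipeline the ULN models are fitted, by default, on a
synthetic healthy **reference bed** with known conditional quantiles
rather than on the cohort's own never-smoker stratum.  The cohort's
never-smokers are calibrated so that 8.2% / 2.9% of them exceed the
true ULN — mirroring the published prevalences, which themselves exceed
the nominal 5% — so refitting τ = 0.95 on that stratum cannot reproduce
those prevalences (the subgradient bound caps the training-set positive
fraction near 5%).  Fitting on an independent healthy reference keeps
the normative surface and the cohort prevalences coherent; training on
the cohort never-smokers remains available via
`normative_training="cohort_neversmokers"`.

## Cohort statistics

Unadjusted comparisons use one-way ANOVA (continuous) and Pearson
chi-square without continuity correction (binary), with pairwise
two-sample t-tests in the Welch unequal-variance form (a pooled-variance
switch exists; the source convention is unstated).  No multiple-testing
correction is applied, matching the presentation of raw pairwise
p-values.  Adjusted tests fit full (group indicators + covariates) and
reduced (covariates only) models and refer the likelihood-ratio
statistic to χ² with (#groups − 1) degrees of freedom: the linear
family uses least squares with the Gaussian profile likelihood
(equivalently n·log RSS-ratio), the logistic family uses Newton/IRLS
with convergence and separation checks; pairwise adjusted comparisons
are Wald tests on group-indicator contrasts.  Missing data are handled
complete-case per analysis with logged exclusion counts.  Sensitivity
and specificity of a threshold rule are computed from the 2×2 table
against CT-defined disease (either metric above its ULN) over all
subjects with both spirometry and CT truth; an empty denominator is
reported as undefined, never as 0.

## Synthetic cohort generator

The generator is first-class, tested code; its defaults *are* the study
conditions: group sizes 161 / 940 / 190 and the published per-group
summaries (age, % male, % white, % current smoker, pack-years,
percent-predicted FEV1 and FEF25–75, 6MWD, SGRQ, CAT, medication /
chronic-bronchitis / dyspnea prevalences, FEV1 slope, exacerbation
rate, CT metric means and SDs, presence prevalences).  Key mechanisms:

* **Constraint satisfaction.**  Demographics are drawn first (ages from
  truncated normals whose *truncated* mean is solved to match the
  target; for the discordant group the lower age bound is the youngest
  age at which LLN(ratio) < 0.70 for that sex/race).  The ratio is then
  drawn inside the group's window — (LLN, 0.70) for discordant,
  (max(0.70, LLN), 0.92) for the unobstructed groups — and FEV1 percent
  predicted from a mean-matched truncated normal floored at the
  subject's normal-FEV1 cut, so every subject satisfies its group's
  rules by construction.  A downstream self-consistency test re-derives
  the labels with the classifier.
* **Skewed CT fractions with exact presence prevalences.**  Group
  fraction distributions are log-normals moment-matched to the
  published mean ± SD (SDs exceed means, ruling out normals).  Each
  subject's presence flags are drawn from a latent bivariate normal
  whose marginals equal the published emphysema/fSAD prevalences and
  whose correlation is solved (bivariate-normal orthant bisection) to
  hit the published "both present" cell; the fraction is then drawn
  from the group log-normal truncated above or below the subject's
  *true* ULN accordingly.  Presence calibration therefore overrides
  exact moment matching of the fractions — the group means of
  %emphysema/%fSAD deviate from the published means (down-weighted
  upper tails), a deliberate trade-off.
* **Copula coupling.**  A single Gaussian-copula parameter (ρ = 0.3 by
  default) links a lower ratio to a higher chance of CT abnormality, so
  threshold-accuracy properties can be exercised; the true joint
  distribution is unknown and the parameter is a modelling choice.
* **Normative truth surface.**  The true ULN of each metric is a linear
  surface in age, sex, BMI and scanner with exponential noise in the
  training bed (right-skewed, mass near zero for emphysema, with the
  τ-quantile known in closed form; clipping to [0, 100] leaves the 95th
  percentile unchanged).  Intercepts/slopes were chosen so the implied
  never-smoker distributions resemble the published never-smoker CT
  summaries and the discordant group's natural exceedance is near its
  published prevalence.
* **Longitudinal visits and events.**  Each subject gets a baseline and
  1–3 follow-ups spanning 266–1749 days, FEV1 trending at a
  subject-level slope drawn from the published ml/year distribution
  plus 15 ml visit noise; exacerbations are Poisson with the group
  rate; symptoms/medication are Bernoulli/truncated-normal draws at the
  published parameters.  Within a group, symptoms are independent of CT
  presence (no joint calibration is published; the corresponding
  within-discordant comparisons are near-null, as observed).
* Paired volumes realize requested fractions by assigning
  `round(frac · n_masked)` voxels per class inside a solid-ellipsoid
  mask, with HU sampled strictly inside each class region; the PRM
  round trip recovers each target within 100/n_masked points.
  Pi10 is realized through 8 synthetic airway measurements on the line
  √WA = a + 0.27·Pi with 0.01 noise.

Everything is deterministic under a fixed seed (single `default_rng`
stream per cohort; per-stage and per-volume seeds derived from the
master seed in the pipeline).

**What the synthetic data does not show.**  Volumes have no anatomy,
texture, scanner physics or registration error; spirometric and CT
marginals are parametric idealizations; the ratio–disease copula and
scanner set (4 uniform labels) are conventions.  Passing tests
demonstrate correctness of the computational chain and internal
calibration, not clinical validity on real cohorts.  Because the
synthetic cohort contains only the three analysis groups (plus an
optional below-LLN stratum), cohort-level sensitivity/specificity
depend on that composition and are not comparable to values estimated
on a full clinical cohort.

## Problem sizes and numerics

Default pipeline volumes are 64³-configurable; the shipped tests and
acceptance script use 16³–48³ ellipsoid masks (≥ 1400 masked voxels, so
voxel quantization is ≤ 0.07 percentage points) and 20 replicate seeds
for Monte-Carlo checks; the reference bed for normative fitting
defaults to n = 1500.  Truncated-normal mean matching solves the
location parameter by 80-step bisection on the closed-form truncated
mean; the presence-correlation orthant equation is solved by bisection
on a deterministic quadrature of the bivariate-normal integral.  HU
thresholds are compared exactly as written on float voxel values.

## Known limitations

* No deformable registration, lung segmentation, DICOM ingestion, or
  airway-tree extraction (Pi10 consumes precomputed measures).
* No GLI-2012 or other reference equations (the coefficient table is
  the pluggable point), no bronchodilator-response computation, no
  spirometry quality grading.
* Quantile models are main-effects linear only; no spline/interaction
  terms, simultaneous multi-quantile fitting, or bootstrap bands.
* No confidence intervals for sensitivity/specificity and no ROC
  analysis over the continuous ratio.
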