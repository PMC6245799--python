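# spiroprm

Quantifying smoking-related lung disease in people whose spirometry sits
on the diagnostic fence.

Airflow obstruction in COPD is confirmed by a reduced ratio of forced
expiratory volume in one second to forced vital capacity (FEV1/FVC).
Clinical practice uses two competing cut-offs: the fixed ratio
FEV1/FVC < 0.70, and the lower limit of normal (LLN), the 5th
percentile of a healthy reference population.  Because the predicted
ratio declines with age, ever-smokers with a normal FEV1 can fall in a
**discordant** zone — FEV1/FVC below 0.70 yet above their LLN — where
the two rules disagree.  `spiroprm` implements the analysis used to
characterize that group: spirometric classification, CT quantification
of emphysema and functional small-airways disease (fSAD) by parametric
response mapping (PRM), quantile-regression normative limits, and the
diagnostic accuracy of each threshold against CT-defined disease.  A
calibrated synthetic-cohort generator supplies study-shaped data so the
whole pipeline is runnable and testable end to end.

The package is aimed at respiratory epidemiologists and methodologists
who want a transparent, reusable implementation of these building
blocks rather than vendor software.

## What it computes

* **Reference spirometry** — NHANES III adult equations
  (polynomial-in-age, height²; stratified by sex and race/ethnicity)
  give predicted values and LLN for FEV1, FVC, FEF25–75 and FEV1/FVC;
  percent predicted is `100 · measured / predicted`.
* **Group classification** — among subjects with normal FEV1:
  discordant (ever-smoker, LLN < FEV1/FVC < 0.70), unobstructed
  ever-smokers and never-smokers (FEV1/FVC > 0.70), plus a cohort-level
  below-LLN quartile group.
* **PRM of paired CT** — within a lung mask, a voxel is *emphysema* if
  inspiratory HU < −950, *fSAD* (non-emphysematous gas trapping) if
  inspiratory HU > −950 and expiratory HU < −856, *normal* otherwise;
  per-subject percentages are reported over masked voxels.  Pi10
  (airway-wall thickness) is the fitted value of √(wall area) at a
  10 mm internal perimeter.
* **Normative upper limit of normal (ULN)** — the covariate-specific
  95th percentile of each PRM metric among healthy never-smokers, fitted
  by linear quantile regression: β̂ minimizes the check loss
  Σ ρ₀.₉₅(yᵢ − xᵢ'β) over age, sex, BMI and scanner, solved as a linear
  program.  Disease is *present* when the observed percentage strictly
  exceeds the ULN.
* **Cohort statistics** — per-group summaries with ANOVA / chi-square
  and pairwise Welch t-tests, covariate-adjusted likelihood-ratio and
  Wald tests (linear and logistic families), annual FEV1 slopes from
  longitudinal visits, exacerbation rates, and sensitivity/specificity
  of the fixed-0.70 and LLN rules against CT-defined disease.

## Worked example

`examples/01_spirometry_groups.py` classifies a 67-year-old male
ever-smoker (FEV1 2.85 L, FVC 4.25 L):

```
FEV1 2.85 L  = 87.0% predicted (LLN 2.38 L)
FEV1/FVC 0.671  (predicted 0.742, LLN 0.645)
analysis group: discordant
-> the fixed 0.70 rule calls this obstruction, the LLN rule does not:
   ratio < 0.70? True;  ratio < LLN? False
```

His FEV1 is normal (87% predicted, above the LLN) and his ratio of
0.671 lies between his LLN of 0.645 and the fixed 0.70 cut-off — the
discordant configuration the package is built to study.

`examples/02_prm_voxels.py` renders a paired CT volume with 2.1%
emphysema-like and 18% gas-trapping voxels and recovers them through the
voxel classifier:

```
masked voxels: 42168
emphysema  (insp < -950 HU):               2.10 %
fSAD (insp > -950 and exp < -856 HU):     18.00 %
normal parenchyma:                        79.90 %
```

The other examples fit the normative ULN model
(`03_normative_uln.py`) and run the whole pipeline on a half-scale
cohort (`04_full_pipeline.py`).  A thin CLI mirrors the stages:

```bash
spiroprm run-all --seed 42 --outdir run --size-factor 0.5
spiroprm simulate --seed 1 --outdir run
spiroprm prm --insp insp.nii.gz --exp exp.nii.gz --mask mask.nii.gz --summary-out prm.json
```

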