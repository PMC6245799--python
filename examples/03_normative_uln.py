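"""Fit the 95th-percentile normative model and classify disease presence.

Generates a healthy reference bed with a known conditional 95th
percentile for each CT metric, fits the quantile-regression model the
package uses for the upper limit of normal (ULN), and classifies one
subject's observed percentages against their covariate-specific ULN.
"""

import pandas as pd

from spiroprm import (
    classify_presence,
    disease_flags,
    fit_normative,
    generate_normative_truth,
    predict_uln,
)

bed = generate_normative_truth(1500, seed=42)
model_e = fit_normative(bed, "pct_emphysema")
model_f = fit_normative(bed, "pct_fsad")
print(f"emphysema model (tau={model_e.tau}, n={model_e.n_train}):")
for name, value in model_e.coef.items():
    print(f"  {name:>20s}  {value:+.4f}")

subject = pd.DataFrame(
    {"age": [69.0], "sex": ["male"], "bmi": [27.5], "scanner": ["scanner_A"]}
)
uln_e = predict_uln(model_e, subject)[0]
uln_f = predict_uln(model_f, subject)[0]
obs_e, obs_f = 2.4, 16.0  # observed % of lung
emph = classify_presence(obs_e, uln_e)
fsad = classify_presence(obs_f, uln_f)
either, both = disease_flags(emph, fsad)
print(f"\n69-year-old man, BMI 27.5: ULN emphysema {uln_e:.2f}%, ULN fSAD {uln_f:.2f}%")
print(f"observed {obs_e}% / {obs_f}% -> emphysema present: {emph}, "
      f"fSAD present: {fsad}, either: {bool(either)}")
print("-> presence means the observed percentage exceeds the 95th percentile")
print("   of healthy never-smokers with the same age, sex, BMI and scanner")
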