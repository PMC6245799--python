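"""Classify one subject against the fixed-ratio and LLN criteria.

Builds a single ever-smoker with borderline airflow obstruction,
computes NHANES III predicted values and lower limits of normal, and
shows why the two diagnostic thresholds disagree for this person.
"""

from spiroprm import classify_group, percent_predicted, predicted_and_lln

age, sex, race, height = 67, "male", "caucasian", 176
fev1, fvc = 2.85, 4.25  # litres, post-bronchodilator

pred_fev1, lln_fev1 = predicted_and_lln(age, sex, race, height, "FEV1")
pred_ratio, lln_ratio = predicted_and_lln(age, sex, race, height, "FEV1/FVC")
ratio = fev1 / fvc

print(f"FEV1 {fev1:.2f} L  = {percent_predicted(fev1, pred_fev1):.1f}% predicted "
      f"(LLN {lln_fev1:.2f} L)")
print(f"FEV1/FVC {ratio:.3f}  (predicted {pred_ratio:.3f}, LLN {lln_ratio:.3f})")

label = classify_group(True, ratio, lln_ratio, fev1, lln_fev1)
print(f"analysis group: {label}")
print("-> the fixed 0.70 rule calls this obstruction, the LLN rule does not:")
print(f"   ratio < 0.70? {ratio < 0.70};  ratio < LLN? {ratio < lln_ratio}")
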