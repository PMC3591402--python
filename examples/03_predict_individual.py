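"""Predict a menopausal-age interval for individual women.

Maps each woman's (age, AMH, BMI, smoking) to an AMH percentile band and
reads the matching percentiles of her covariate cell's menopausal-age
distribution.
"""

import menopredict as mp
from menopredict.menopause import CovariateProfile

cfg = mp.default_generating_params(seed=0)
rm, tm = cfg.regression, cfg.threshold_model

women = [
    ("30 y, AMH 2.5, BMI 22, non-smoker", 30.0, 2.5, 22.0, False),
    ("30 y, AMH 2.5, BMI 27, non-smoker", 30.0, 2.5, 27.0, False),
    ("30 y, AMH 2.5, BMI 22, smoker", 30.0, 2.5, 22.0, True),
    ("35 y, AMH 0.5, BMI 22, non-smoker", 35.0, 0.5, 22.0, False),
]

for label, age, amh, bmi, smoker in women:
    profile = CovariateProfile.from_bmi(bmi, smoker)
    pred = mp.predict_menopause_interval(age, amh, profile, rm, tm)
    hi = "open" if pred.unbounded_high else f"{pred.age_high:.1f}"
    print(f"{label:36s} band ({int(pred.band[0]*100)}%, {int(pred.band[1]*100)}%] "
          f"-> menopause {pred.age_low:.1f}-{hi} y")

print("\nHigher BMI shifts the predicted interval later (lower AMH threshold);")
print("smoking shifts it about a year earlier; a low AMH for age narrows the")
print("remaining reproductive lifespan estimate.")
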