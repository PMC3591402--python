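"""Age-dependent AMH reference percentiles from the calibrated model.

Builds the calibrated default model (log-AMH quadratic in age, peaking at
25, with mean-zero left-skewed skew-t residuals) and prints the reference
percentile curves a clinician would read a measurement against.
"""

import menopredict as mp

cfg = mp.default_generating_params(seed=0)
rm = cfg.regression

table = mp.amh_percentile_curves(rm, ages=[25, 30, 35, 40, 45])
print("AMH reference percentiles (ng/mL) by age:")
print(table.to_frame().round(2))

band = mp.percentile_band(rm, 30.0, 2.5)
print(
    f"\nA measurement of 2.5 ng/mL at age 30 falls in the "
    f"({int(band[0]*100)}%, {int(band[1]*100)}%] band: "
    "below the median for her age but above the 25th percentile."
)
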