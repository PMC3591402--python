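# Declarative pipeline configuration for `menopredict run-all --config ...`.
# All seeds, sizes and probability grids live here, never in code.
schema_version: 1
seed: 1
simulate:
  n_amh: 375        # AMH cohort size
  n_meno: 2635      # menopausal-age cohort size
fit:
  terms: [age, age2]
  n_starts: 5
percentiles:
  probs: [0.05, 0.10, 0.25, 0.50, 0.75, 0.90, 0.95]
predictions:
  - {age_years: 30, amh_ng_ml: 2.5, bmi: 22.0, smoker: 0}
  - {age_years: 30, amh_ng_ml: 2.5, bmi: 27.0, smoker: 0}
  - {age_years: 30, amh_ng_ml: 2.5, bmi: 22.0, smoker: 1}
# To analyse real cohorts instead of simulating, point the pipeline at
# validated CSVs (see README for the column schemas):
# inputs:
#   amh_csv: path/to/amh_cohort.csv
#   menopause_csv: path/to/menopause_cohort.csv
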