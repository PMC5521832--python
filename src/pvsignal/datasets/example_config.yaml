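# Example pipeline configuration: simulate a 50,000-report database with
# one drug that truly elevates thromboembolism reporting (odds x 40) and a
# drospirenone-like wear-out onset profile, then run the full screen.
output_dir: pvsignal-out
seed: 42
drugs: [Drospirenone-EE]
combined_label: All study drugs
simulate:
  n_reports: 50000
  background_te_rate: 0.043
  drugs:
    - name: Drospirenone-EE
      exposure_prevalence: 0.003
      te_odds_multiplier: 40.0
      tto_scale_alpha: 223.8
      tto_shape_beta: 1.12
      age_distribution:
        "10-19": 0.04
        "20-29": 0.17
        "30-39": 0.31
        "40-49": 0.35
        "50-59": 0.13
min_support: 0.00001
min_confidence: 0.9
maxlen: 3
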