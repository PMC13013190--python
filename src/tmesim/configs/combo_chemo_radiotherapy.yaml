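# Docetaxel Q3W from day 0 with radiotherapy starting at day 25.
lattice_extents: [24, 24, 24]
initial_cancer: 100
immune_ratio: 0.01
horizon_days: 60
dt_h: 0.5
seed: 0
regimens:
  - modality: docetaxel
    amount: 0.132
    pattern: q3w
    start_day: 0
    n_doses: 3
  - modality: radiation
    amount: 2.5
    pattern: 5_per_week
    start_day: 25
    duration_weeks: 2
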