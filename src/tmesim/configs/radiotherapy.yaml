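# Radiotherapy 2.5 Gy, 5 days/week for 4 weeks (reduced course) on an
# established dense tumour; treatment starts at day 7.
lattice_extents: [24, 24, 24]
initial_cancer: 400
immune_ratio: 0.01
horizon_days: 49
dt_h: 0.5
seed: 0
regimens:
  - modality: radiation
    amount: 2.5          # Gy per fraction
    pattern: 5_per_week
    start_day: 7
    duration_weeks: 4
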