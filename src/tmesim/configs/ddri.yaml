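# DNA-damage-response inhibitor 210 mg/m^2 weekly (from day 14).
lattice_extents: [24, 24, 24]
initial_cancer: 100
immune_ratio: 0.01
horizon_days: 49
dt_h: 0.5
output:
  census_interval_h: 6.0
seed: 0
regimens:
  - modality: ddri
    amount: 210.0        # mg/m^2 (converted with BSA 1.75 m^2)
    pattern: weekly
    start_day: 14
    n_doses: 5
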