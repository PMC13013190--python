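# PD1 antibody 2 mg/kg Q3W (reduced horizon; treatment from day 20).
lattice_extents: [24, 24, 24]
initial_cancer: 100
immune_ratio: 0.01
horizon_days: 60
dt_h: 0.5
seed: 0
regimens:
  - modality: pd1_antibody
    amount: 2.0          # mg/kg
    pattern: q3w
    start_day: 20
    n_doses: 2
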