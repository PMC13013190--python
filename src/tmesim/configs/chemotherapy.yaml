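# Docetaxel 0.132 g Q3W (printed dose for BSA 1.75 m^2 at 75 mg/m^2).
lattice_extents: [24, 24, 24]
initial_cancer: 100
immune_ratio: 0.01
horizon_days: 60
dt_h: 0.5
seed: 0
regimens:
  - modality: docetaxel
    amount: 0.132        # g
    pattern: q3w
    start_day: 10
    n_doses: 3
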