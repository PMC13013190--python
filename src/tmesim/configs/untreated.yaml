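# Untreated tumour growth: 100 cancer agents (0.1 cm^3), 1:100 immune seeding.
lattice_extents: [24, 24, 24]
initial_cancer: 100
immune_ratio: 0.01
horizon_days: 60
dt_h: 0.5
seed: 0
regimens: []
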