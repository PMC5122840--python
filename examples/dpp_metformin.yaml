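# Single-SNP x metformin DPP scenario: power at the trial's actual size,
# and the minimum sizes reaching 80% power under both recruitment designs.
seed: 1
scenarios:
  - name: dpp_power
    preset: dpp-metformin-slc47a1
    iterations: 1000
  - name: dpp_gbr_n80
    preset: dpp-metformin-slc47a1
    design: gbr
    task: sample_size
    target_power: 0.8
    iterations_per_point: 300
  - name: dpp_conventional_n80
    preset: dpp-metformin-slc47a1
    task: sample_size
    target_power: 0.8
    iterations_per_point: 300
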