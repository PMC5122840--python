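# The four 20-SNP GRS scenario families (Cox outcome, frame 10,000),
# crossed with both recruitment designs.
seed: 1
cap: 16
base:
  frame_size: 10000
  n_trial: 500
  outcome: survival
  k: 20
  iterations: 300
axes:
  design: [conventional, gbr]
  maf_range: [[0.05, 0.2], [0.2, 0.5]]
  effect_range: [[0.05, 0.15], [0.15, 0.30]]
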