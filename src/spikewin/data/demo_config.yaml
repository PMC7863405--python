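# Bundled demo: simulation-backed end-to-end run (solvent / 8 h / 18 h).
seed: 7
output_dir: spikewin_demo_out
simulation:
  n_replicates: 3
  depth: 40000
  technical_sd: 0.3
  duplication_rate: 0.10
counting:
  width: 150
  step: 50
  max_fragment: 500
  background_bin: 1000
  min_fold: 3.0
normalization:
  ruv_k: 1
  mode: ruv
differential:
  max_gap: 100
  max_width: 5000
  fold: 1.5
  q: 0.05
  contrast: anova
compartments:
  enabled: true
  bin_width: 50000
  reference: solvent
states:
  enabled: true
  simulate: true
  n_patients: 19
  min_fraction: 0.5
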