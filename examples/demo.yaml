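# Demo pipeline configuration: full synthetic run at small scale.
# `crzpulse run-all --config examples/demo.yaml --out demo_out`
seed: 7
output_dir: demo_out
stages:
  - generate
  - detect
  - analyze
  - simulate_tdm
  - simulate_csm
  - fit_pulses
  - periodicity
generator:
  n_cells: 8
  duration_sec: 2400
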