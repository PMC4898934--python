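# Demo experiment: simulate small cohorts of every live-imaging condition,
# quantify them end-to-end, and write cells.csv + manifest.yaml.
# Run with:  sirs-quant run --config configs/demo.yaml
output_dir: results/demo
seed: 1
presets:
  - {preset: pre_division, n: 3}
  - {preset: wt_timing, n: 3}
  - {preset: mad2_timing, n: 3}
  - {preset: diplo_division, n: 3}
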