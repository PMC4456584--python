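# MI-gain (disinhibition) sweep at the coupled point, written out as CSV/JSON.
preset: fig8
model: rate
seed: 0
out_dir: results/fig8
overrides:
  drive_max: 300.0
  n_grid: 13
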