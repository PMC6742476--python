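# Nutrient downshift, reduced ensemble for a quick run:
#   rodshape shift --config examples/shift_downshift.yaml --out-dir run/
seed: 1
model:
  delta_sigma: 0.05
protocol:
  n_cells: 500
  burn_in: 8
  k_pre: 0.75
  k_post: 0.25
  duration: 18.0
  record_start: -2.0
  bin_minutes: 10.0
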