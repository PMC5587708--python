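n_fields: 10
model:
  cell_count: 5
  cell_radius_um: 10.0
  green_density: 0.2      # marker puncta per um^2 of cytoplasm
  red_density: 0.02       # PLA puncta per um^2
  coupling_fraction: 0.8
  offset_law: {fixed: 0.3}
proximity:
  n_cells: 50
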