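# Approximate reference adult male phantom organ masses (g), in the style of
# the standard stylized reference-phantom series. Values are rounded
# literature-typical masses; only internal consistency is asserted in tests.
model_id: adult_male
sex: male
total_body_mass_g: 73700
smatrix: smatrix_adult_male.csv
organ_masses_g:
  adrenals: 16.3
  brain: 1420
  breasts: 26
  gallbladder_wall: 10.5
  stomach_wall: 158
  heart_wall: 316
  kidneys: 299
  lower_large_intestine_wall: 167
  upper_large_intestine_wall: 220
  small_intestine: 677
  liver: 1910
  lungs: 1000
  muscle: 28000
  pancreas: 94.3
  red_marrow: 1120
  osteogenic_cells: 120
  skin: 3010
  spleen: 183
  testes: 39.1
  thymus: 20.9
  thyroid: 20.7
  urinary_bladder_wall: 47.6
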