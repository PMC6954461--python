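# Approximate 5-year-old reference phantom organ masses (g).
model_id: five_year
sex: both
total_body_mass_g: 19800
smatrix: smatrix_five_year.csv
organ_masses_g:
  adrenals: 5.3
  brain: 1260
  breasts: 2.6
  gallbladder_wall: 2.6
  stomach_wall: 49.1
  heart_wall: 92.8
  kidneys: 116
  lower_large_intestine_wall: 36.6
  upper_large_intestine_wall: 49.4
  small_intestine: 220
  liver: 584
  lungs: 290
  muscle: 5000
  ovaries: 1.7
  pancreas: 23.6
  red_marrow: 320
  osteogenic_cells: 60
  skin: 538
  spleen: 48.3
  testes: 1.6
  thymus: 29.6
  thyroid: 3.45
  urinary_bladder_wall: 14.5
  uterus: 2.7
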