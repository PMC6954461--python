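# Approximate 1-year-old reference phantom organ masses (g).
model_id: one_year
sex: both
total_body_mass_g: 9720
smatrix: smatrix_one_year.csv
organ_masses_g:
  adrenals: 3.5
  brain: 884
  breasts: 1.5
  gallbladder_wall: 1.4
  stomach_wall: 21.8
  heart_wall: 50.6
  kidneys: 62.9
  lower_large_intestine_wall: 20.6
  upper_large_intestine_wall: 28.8
  small_intestine: 95
  liver: 292
  lungs: 143
  muscle: 2200
  ovaries: 0.71
  pancreas: 10.3
  red_marrow: 150
  osteogenic_cells: 30
  skin: 271
  spleen: 25.5
  testes: 1.5
  thymus: 22.9
  thyroid: 1.78
  urinary_bladder_wall: 7.7
  uterus: 1.45
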