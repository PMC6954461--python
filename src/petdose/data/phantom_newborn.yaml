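# Approximate newborn reference phantom organ masses (g). Pediatric models
# carry both gonad sets (two-sex stylized phantom convention).
model_id: newborn
sex: both
total_body_mass_g: 3536
smatrix: smatrix_newborn.csv
organ_masses_g:
  adrenals: 5.8
  brain: 352
  breasts: 0.7
  gallbladder_wall: 0.5
  stomach_wall: 6.4
  heart_wall: 25.4
  kidneys: 22.9
  lower_large_intestine_wall: 7.0
  upper_large_intestine_wall: 10.5
  small_intestine: 32.6
  liver: 121
  lungs: 50.6
  muscle: 760
  ovaries: 0.33
  pancreas: 2.8
  red_marrow: 47
  osteogenic_cells: 15
  skin: 118
  spleen: 9.1
  testes: 0.84
  thymus: 11.3
  thyroid: 1.29
  urinary_bladder_wall: 2.9
  uterus: 3.85
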