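# Approximate reference adult female phantom organ masses (g); see the adult
# male file for provenance conventions.
model_id: adult_female
sex: female
total_body_mass_g: 56800
smatrix: smatrix_adult_female.csv
organ_masses_g:
  adrenals: 14.0
  brain: 1200
  breasts: 360
  gallbladder_wall: 8.0
  stomach_wall: 140
  heart_wall: 240
  kidneys: 275
  lower_large_intestine_wall: 160
  upper_large_intestine_wall: 210
  small_intestine: 600
  liver: 1400
  lungs: 800
  muscle: 17000
  ovaries: 11.0
  pancreas: 85.0
  red_marrow: 1050
  osteogenic_cells: 100
  skin: 2300
  spleen: 150
  thymus: 19.0
  thyroid: 17.0
  urinary_bladder_wall: 35.9
  uterus: 80.0
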