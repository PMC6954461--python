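# ICRP-60 tissue weighting factors (sum = 1) with the organ-resolution rules
# used when a weighted tissue has no direct row in the phantom tables:
#   colon       -> mass-weighted mean of upper + lower large intestine walls
#   oesophagus  -> thymus surrogate
#   bone_surface-> osteogenic cells
#   gonads      -> sex-matched (ovaries preferred on two-sex pediatric models)
# remainder = mass-weighted mean dose of the listed remainder tissues.
scheme: icrp60
weights:
  gonads: 0.20
  red_marrow: 0.12
  colon: 0.12
  lungs: 0.12
  stomach_wall: 0.12
  urinary_bladder_wall: 0.05
  breasts: 0.05
  liver: 0.05
  oesophagus: 0.05
  thyroid: 0.05
  skin: 0.01
  bone_surface: 0.01
  remainder: 0.05
composite:
  colon: [upper_large_intestine_wall, lower_large_intestine_wall]
surrogate:
  oesophagus: thymus
  bone_surface: osteogenic_cells
gonads: [ovaries, testes]
remainder_tissues:
  - adrenals
  - brain
  - kidneys
  - muscle
  - pancreas
  - small_intestine
  - spleen
  - thymus
  - uterus
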