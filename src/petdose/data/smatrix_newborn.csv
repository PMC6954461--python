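# Approximate S values (mGy per MBq h) generated by scripts/build_smatrices.py
# model: newborn; sphere-equivalent self-absorption + point-pair photon cross-fire
target,source,s_mGy_per_MBq_h
adrenals,kidneys,1.18883
adrenals,pancreas,0.292734
adrenals,small_intestine,0.0694023
adrenals,total_body,0.153568
brain,kidneys,0.0027424
brain,pancreas,0.0027424
brain,small_intestine,0.00198218
brain,total_body,0.153568
breasts,kidneys,0.013266
breasts,pancreas,0.0180063
breasts,small_intestine,0.013266
breasts,total_body,0.153568
gallbladder_wall,kidneys,0.16227
gallbladder_wall,pancreas,0.213591
gallbladder_wall,small_intestine,0.102021
gallbladder_wall,total_body,0.153568
stomach_wall,kidneys,0.213591
stomach_wall,pancreas,0.424081
stomach_wall,small_intestine,0.0694023
stomach_wall,total_body,0.153568
heart_wall,kidneys,0.022479
heart_wall,pancreas,0.0285822
heart_wall,small_intestine,0.013266
heart_wall,total_body,0.153568
kidneys,kidneys,19.6789
kidneys,pancreas,0.213591
kidneys,small_intestine,0.0694023
kidneys,total_body,0.153568
lower_large_intestine_wall,kidneys,0.0428629
lower_large_intestine_wall,pancreas,0.0285822
lower_large_intestine_wall,small_intestine,0.16227
lower_large_intestine_wall,total_body,0.153568
upper_large_intestine_wall,kidneys,0.102021
upper_large_intestine_wall,pancreas,0.102021
upper_large_intestine_wall,small_intestine,0.292734
upper_large_intestine_wall,total_body,0.153568
small_intestine,kidneys,0.0694023
small_intestine,pancreas,0.127125
small_intestine,small_intestine,13.9126
small_intestine,total_body,0.153568
liver,kidneys,0.16227
liver,pancreas,0.16227
liver,small_intestine,0.0694023
liver,total_body,0.153568
lungs,kidneys,0.0285822
lungs,pancreas,0.0371855
lungs,small_intestine,0.0180063
lungs,total_body,0.153568
muscle,kidneys,0.0428629
muscle,pancreas,0.0428629
muscle,small_intestine,0.0428629
muscle,total_body,0.153568
ovaries,kidneys,0.0428629
ovaries,pancreas,0.0285822
ovaries,small_intestine,0.16227
ovaries,total_body,0.153568
pancreas,kidneys,0.213591
pancreas,pancreas,156.707
pancreas,small_intestine,0.127125
pancreas,total_body,0.153568
red_marrow,kidneys,0.0428629
red_marrow,pancreas,0.0428629
red_marrow,small_intestine,0.0428629
red_marrow,total_body,0.153568
osteogenic_cells,kidneys,0.0428629
osteogenic_cells,pancreas,0.0428629
osteogenic_cells,small_intestine,0.0428629
osteogenic_cells,total_body,0.153568
skin,kidneys,0.0285822
skin,pancreas,0.0285822
skin,small_intestine,0.0285822
skin,total_body,0.153568
spleen,kidneys,0.292734
spleen,pancreas,0.16227
spleen,small_intestine,0.0498218
spleen,total_body,0.153568
testes,kidneys,0.013266
testes,pancreas,0.0100289
testes,small_intestine,0.0285822
testes,total_body,0.153568
thymus,kidneys,0.013266
thymus,pancreas,0.0162093
thymus,small_intestine,0.0100289
thymus,total_body,0.153568
thyroid,kidneys,0.00561031
thyroid,pancreas,0.00656748
thyroid,small_intestine,0.00447496
thyroid,total_body,0.153568
urinary_bladder_wall,kidneys,0.0285822
urinary_bladder_wall,pancreas,0.022479
urinary_bladder_wall,small_intestine,0.102021
urinary_bladder_wall,total_body,0.153568
uterus,kidneys,0.0371855
uterus,pancreas,0.0252832
uterus,small_intestine,0.127125
uterus,total_body,0.153568
total_body,kidneys,0.153568
total_body,pancreas,0.153568
total_body,small_intestine,0.153568
total_body,total_body,0.153568
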