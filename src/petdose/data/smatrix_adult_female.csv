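# Approximate S values (mGy per MBq h) generated by scripts/build_smatrices.py
# model: adult_female; sphere-equivalent self-absorption + point-pair photon cross-fire
target,source,s_mGy_per_MBq_h
adrenals,kidneys,0.181876
adrenals,pancreas,0.0420048
adrenals,small_intestine,0.00822181
adrenals,total_body,0.0118685
brain,kidneys,7.13456e-05
brain,pancreas,7.13456e-05
brain,small_intestine,4.01522e-05
brain,total_body,0.0118685
breasts,kidneys,0.000908057
breasts,pancreas,0.0014119
breasts,small_intestine,0.000908057
breasts,total_body,0.0118685
gallbladder_wall,kidneys,0.022006
gallbladder_wall,pancreas,0.0298289
gallbladder_wall,small_intestine,0.0129717
gallbladder_wall,total_body,0.0118685
stomach_wall,kidneys,0.0298289
stomach_wall,pancreas,0.0623621
stomach_wall,small_intestine,0.00822181
stomach_wall,total_body,0.0118685
heart_wall,kidneys,0.00192511
heart_wall,pancreas,0.00266728
heart_wall,small_intestine,0.000908057
heart_wall,total_body,0.0118685
kidneys,kidneys,1.74491
kidneys,pancreas,0.0298289
kidneys,small_intestine,0.00822181
kidneys,total_body,0.0118685
lower_large_intestine_wall,kidneys,0.0045255
lower_large_intestine_wall,pancreas,0.00266728
lower_large_intestine_wall,small_intestine,0.022006
lower_large_intestine_wall,total_body,0.0118685
upper_large_intestine_wall,kidneys,0.0129717
upper_large_intestine_wall,pancreas,0.0129717
upper_large_intestine_wall,small_intestine,0.0420048
upper_large_intestine_wall,total_body,0.0118685
small_intestine,kidneys,0.00822181
small_intestine,pancreas,0.0167077
small_intestine,small_intestine,0.824299
small_intestine,total_body,0.0118685
liver,kidneys,0.022006
liver,pancreas,0.022006
liver,small_intestine,0.00822181
liver,total_body,0.0118685
lungs,kidneys,0.00266728
lungs,pancreas,0.00377084
lungs,small_intestine,0.0014119
lungs,total_body,0.0118685
muscle,kidneys,0.0045255
muscle,pancreas,0.0045255
muscle,small_intestine,0.0045255
muscle,total_body,0.0118685
ovaries,kidneys,0.0045255
ovaries,pancreas,0.00266728
ovaries,small_intestine,0.022006
ovaries,total_body,0.0118685
pancreas,kidneys,0.0298289
pancreas,pancreas,5.45019
pancreas,small_intestine,0.0167077
pancreas,total_body,0.0118685
red_marrow,kidneys,0.0045255
red_marrow,pancreas,0.0045255
red_marrow,small_intestine,0.0045255
red_marrow,total_body,0.0118685
osteogenic_cells,kidneys,0.0045255
osteogenic_cells,pancreas,0.0045255
osteogenic_cells,small_intestine,0.0045255
osteogenic_cells,total_body,0.0118685
skin,kidneys,0.00266728
skin,pancreas,0.00266728
skin,small_intestine,0.00266728
skin,total_body,0.0118685
spleen,kidneys,0.0420048
spleen,pancreas,0.022006
spleen,small_intestine,0.00547178
spleen,total_body,0.0118685
thymus,kidneys,0.000908057
thymus,pancreas,0.00121525
thymus,small_intestine,0.000597188
thymus,total_body,0.0118685
thyroid,kidneys,0.000239002
thyroid,pancreas,0.000308221
thyroid,small_intestine,0.000164646
thyroid,total_body,0.0118685
urinary_bladder_wall,kidneys,0.00266728
urinary_bladder_wall,pancreas,0.00192511
urinary_bladder_wall,small_intestine,0.0129717
urinary_bladder_wall,total_body,0.0118685
uterus,kidneys,0.00377084
uterus,pancreas,0.00226096
uterus,small_intestine,0.0167077
uterus,total_body,0.0118685
total_body,kidneys,0.0118685
total_body,pancreas,0.0118685
total_body,small_intestine,0.0118685
total_body,total_body,0.0118685
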