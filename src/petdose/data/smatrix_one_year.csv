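# Approximate S values (mGy per MBq h) generated by scripts/build_smatrices.py
# model: one_year; sphere-equivalent self-absorption + point-pair photon cross-fire
target,source,s_mGy_per_MBq_h
adrenals,kidneys,0.602795
adrenals,pancreas,0.146517
adrenals,small_intestine,0.0333226
adrenals,total_body,0.0599069
brain,kidneys,0.000910215
brain,pancreas,0.000910215
brain,small_intestine,0.000617174
brain,total_body,0.0599069
breasts,kidneys,0.00560134
breasts,pancreas,0.00785515
breasts,small_intestine,0.00560134
breasts,total_body,0.0599069
gallbladder_wall,kidneys,0.0802561
gallbladder_wall,pancreas,0.1063
gallbladder_wall,small_intestine,0.049758
gallbladder_wall,total_body,0.0599069
stomach_wall,kidneys,0.1063
stomach_wall,pancreas,0.213332
stomach_wall,small_intestine,0.0333226
stomach_wall,total_body,0.0599069
heart_wall,kidneys,0.010014
heart_wall,pancreas,0.0129927
heart_wall,small_intestine,0.00560134
heart_wall,total_body,0.0599069
kidneys,kidneys,7.31151
kidneys,pancreas,0.1063
kidneys,small_intestine,0.0333226
kidneys,total_body,0.0599069
lower_large_intestine_wall,kidneys,0.0200497
lower_large_intestine_wall,pancreas,0.0129927
lower_large_intestine_wall,small_intestine,0.0802561
lower_large_intestine_wall,total_body,0.0599069
upper_large_intestine_wall,kidneys,0.049758
upper_large_intestine_wall,pancreas,0.049758
upper_large_intestine_wall,small_intestine,0.146517
upper_large_intestine_wall,total_body,0.0599069
small_intestine,kidneys,0.0333226
small_intestine,pancreas,0.0624508
small_intestine,small_intestine,4.89046
small_intestine,total_body,0.0599069
liver,kidneys,0.0802561
liver,pancreas,0.0802561
liver,small_intestine,0.0333226
liver,total_body,0.0599069
lungs,kidneys,0.0129927
lungs,pancreas,0.0172333
lungs,small_intestine,0.00785515
lungs,total_body,0.0599069
muscle,kidneys,0.0200497
muscle,pancreas,0.0200497
muscle,small_intestine,0.0200497
muscle,total_body,0.0599069
ovaries,kidneys,0.0200497
ovaries,pancreas,0.0129927
ovaries,small_intestine,0.0802561
ovaries,total_body,0.0599069
pancreas,kidneys,0.1063
pancreas,pancreas,43.2205
pancreas,small_intestine,0.0624508
pancreas,total_body,0.0599069
red_marrow,kidneys,0.0200497
red_marrow,pancreas,0.0200497
red_marrow,small_intestine,0.0200497
red_marrow,total_body,0.0599069
osteogenic_cells,kidneys,0.0200497
osteogenic_cells,pancreas,0.0200497
osteogenic_cells,small_intestine,0.0200497
osteogenic_cells,total_body,0.0599069
skin,kidneys,0.0129927
skin,pancreas,0.0129927
skin,small_intestine,0.0129927
skin,total_body,0.0599069
spleen,kidneys,0.146517
spleen,pancreas,0.0802561
spleen,small_intestine,0.0235158
spleen,total_body,0.0599069
testes,kidneys,0.00560134
testes,pancreas,0.00409351
testes,small_intestine,0.0129927
testes,total_body,0.0599069
thymus,kidneys,0.00560134
thymus,pancreas,0.00699574
thymus,small_intestine,0.00409351
thymus,total_body,0.0599069
thyroid,kidneys,0.00210829
thyroid,pancreas,0.00252808
thyroid,small_intestine,0.00162114
thyroid,total_body,0.0599069
urinary_bladder_wall,kidneys,0.0129927
urinary_bladder_wall,pancreas,0.010014
urinary_bladder_wall,small_intestine,0.049758
urinary_bladder_wall,total_body,0.0599069
uterus,kidneys,0.0172333
uterus,pancreas,0.0113787
uterus,small_intestine,0.0624508
uterus,total_body,0.0599069
total_body,kidneys,0.0599069
total_body,pancreas,0.0599069
total_body,small_intestine,0.0599069
total_body,total_body,0.0599069
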