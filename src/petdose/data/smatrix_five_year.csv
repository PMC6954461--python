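# Approximate S values (mGy per MBq h) generated by scripts/build_smatrices.py
# model: five_year; sphere-equivalent self-absorption + point-pair photon cross-fire
target,source,s_mGy_per_MBq_h
adrenals,kidneys,0.372878
adrenals,pancreas,0.0892932
adrenals,small_intestine,0.0194047
adrenals,total_body,0.0310993
brain,kidneys,0.000366096
brain,pancreas,0.000366096
brain,small_intestine,0.000233381
brain,total_body,0.0310993
breasts,kidneys,0.00285609
breasts,pancreas,0.00414004
breasts,small_intestine,0.00285609
breasts,total_body,0.0310993
gallbladder_wall,kidneys,0.0482649
gallbladder_wall,pancreas,0.0643719
gallbladder_wall,small_intestine,0.0294693
gallbladder_wall,total_body,0.0310993
stomach_wall,kidneys,0.0643719
stomach_wall,pancreas,0.13076
stomach_wall,small_intestine,0.0194047
stomach_wall,total_body,0.0310993
heart_wall,kidneys,0.00539219
heart_wall,pancreas,0.00714328
heart_wall,small_intestine,0.00285609
heart_wall,total_body,0.0310993
kidneys,kidneys,4.02669
kidneys,pancreas,0.0643719
kidneys,small_intestine,0.0194047
kidneys,total_body,0.0310993
lower_large_intestine_wall,kidneys,0.0113569
lower_large_intestine_wall,pancreas,0.00714328
lower_large_intestine_wall,small_intestine,0.0482649
lower_large_intestine_wall,total_body,0.0310993
upper_large_intestine_wall,kidneys,0.0294693
upper_large_intestine_wall,pancreas,0.0294693
upper_large_intestine_wall,small_intestine,0.0892932
upper_large_intestine_wall,total_body,0.0310993
small_intestine,kidneys,0.0194047
small_intestine,pancreas,0.037279
small_intestine,small_intestine,2.16466
small_intestine,total_body,0.0310993
liver,kidneys,0.0482649
liver,pancreas,0.0482649
liver,small_intestine,0.0194047
liver,total_body,0.0310993
lungs,kidneys,0.00714328
lungs,pancreas,0.00966701
lungs,small_intestine,0.00414004
lungs,total_body,0.0310993
muscle,kidneys,0.0113569
muscle,pancreas,0.0113569
muscle,small_intestine,0.0113569
muscle,total_body,0.0310993
ovaries,kidneys,0.0113569
ovaries,pancreas,0.00714328
ovaries,small_intestine,0.0482649
ovaries,total_body,0.0310993
pancreas,kidneys,0.0643719
pancreas,pancreas,19.1052
pancreas,small_intestine,0.037279
pancreas,total_body,0.0310993
red_marrow,kidneys,0.0113569
red_marrow,pancreas,0.0113569
red_marrow,small_intestine,0.0113569
red_marrow,total_body,0.0310993
osteogenic_cells,kidneys,0.0113569
osteogenic_cells,pancreas,0.0113569
osteogenic_cells,small_intestine,0.0113569
osteogenic_cells,total_body,0.0310993
skin,kidneys,0.00714328
skin,pancreas,0.00714328
skin,small_intestine,0.00714328
skin,total_body,0.0310993
spleen,kidneys,0.0892932
spleen,pancreas,0.0482649
spleen,small_intestine,0.0134473
spleen,total_body,0.0310993
testes,kidneys,0.00285609
testes,pancreas,0.00201746
testes,small_intestine,0.00714328
testes,total_body,0.0310993
thymus,kidneys,0.00285609
thymus,pancreas,0.00364707
thymus,small_intestine,0.00201746
thymus,total_body,0.0310993
thyroid,kidneys,0.000957257
thyroid,pancreas,0.00117543
thyroid,small_intestine,0.000710063
thyroid,total_body,0.0310993
urinary_bladder_wall,kidneys,0.00714328
urinary_bladder_wall,pancreas,0.00539219
urinary_bladder_wall,small_intestine,0.0294693
urinary_bladder_wall,total_body,0.0310993
uterus,kidneys,0.00966701
uterus,pancreas,0.00619165
uterus,small_intestine,0.037279
uterus,total_body,0.0310993
total_body,kidneys,0.0310993
total_body,pancreas,0.0310993
total_body,small_intestine,0.0310993
total_body,total_body,0.0310993
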