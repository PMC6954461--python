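# Approximate S values (mGy per MBq h) generated by scripts/build_smatrices.py
# model: adult_male; sphere-equivalent self-absorption + point-pair photon cross-fire
target,source,s_mGy_per_MBq_h
adrenals,kidneys,0.15204
adrenals,pancreas,0.0346757
adrenals,small_intestine,0.00655471
adrenals,total_body,0.00936233
brain,kidneys,4.45705e-05
brain,pancreas,4.45705e-05
brain,small_intestine,2.41463e-05
brain,total_body,0.00936233
breasts,kidneys,0.000660356
breasts,pancreas,0.00104977
breasts,small_intestine,0.000660356
breasts,total_body,0.00936233
gallbladder_wall,kidneys,0.0179752
gallbladder_wall,pancreas,0.0244986
gallbladder_wall,small_intestine,0.0104722
gallbladder_wall,total_body,0.00936233
stomach_wall,kidneys,0.0244986
stomach_wall,pancreas,0.0517242
stomach_wall,small_intestine,0.00655471
stomach_wall,total_body,0.00936233
heart_wall,kidneys,0.00145233
heart_wall,pancreas,0.00204126
heart_wall,small_intestine,0.000660356
heart_wall,total_body,0.00936233
kidneys,kidneys,1.6096
kidneys,pancreas,0.0244986
kidneys,small_intestine,0.00655471
kidneys,total_body,0.00936233
lower_large_intestine_wall,kidneys,0.00353656
lower_large_intestine_wall,pancreas,0.00204126
lower_large_intestine_wall,small_intestine,0.0179752
lower_large_intestine_wall,total_body,0.00936233
upper_large_intestine_wall,kidneys,0.0104722
upper_large_intestine_wall,pancreas,0.0104722
upper_large_intestine_wall,small_intestine,0.0346757
upper_large_intestine_wall,total_body,0.00936233
small_intestine,kidneys,0.00655471
small_intestine,pancreas,0.0135693
small_intestine,small_intestine,0.734378
small_intestine,total_body,0.00936233
liver,kidneys,0.0179752
liver,pancreas,0.0179752
liver,small_intestine,0.00655471
liver,total_body,0.00936233
lungs,kidneys,0.00204126
lungs,pancreas,0.0029266
lungs,small_intestine,0.00104977
lungs,total_body,0.00936233
muscle,kidneys,0.00353656
muscle,pancreas,0.00353656
muscle,small_intestine,0.00353656
muscle,total_body,0.00936233
pancreas,kidneys,0.0244986
pancreas,pancreas,4.92581
pancreas,small_intestine,0.0135693
pancreas,total_body,0.00936233
red_marrow,kidneys,0.00353656
red_marrow,pancreas,0.00353656
red_marrow,small_intestine,0.00353656
red_marrow,total_body,0.00936233
osteogenic_cells,kidneys,0.00353656
osteogenic_cells,pancreas,0.00353656
osteogenic_cells,small_intestine,0.00353656
osteogenic_cells,total_body,0.00936233
skin,kidneys,0.00204126
skin,pancreas,0.00204126
skin,small_intestine,0.00204126
skin,total_body,0.00936233
spleen,kidneys,0.0346757
spleen,pancreas,0.0179752
spleen,small_intestine,0.00430515
spleen,total_body,0.00936233
testes,kidneys,0.000660356
testes,pancreas,0.000424643
testes,small_intestine,0.00204126
testes,total_body,0.00936233
thymus,kidneys,0.000660356
thymus,pancreas,0.000896939
thymus,small_intestine,0.000424643
thymus,total_body,0.00936233
thyroid,kidneys,0.000161162
thyroid,pancreas,0.000211027
thyroid,small_intestine,0.000108509
thyroid,total_body,0.00936233
urinary_bladder_wall,kidneys,0.00204126
urinary_bladder_wall,pancreas,0.00145233
urinary_bladder_wall,small_intestine,0.0104722
urinary_bladder_wall,total_body,0.00936233
total_body,kidneys,0.00936233
total_body,pancreas,0.00936233
total_body,small_intestine,0.00936233
total_body,total_body,0.00936233
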