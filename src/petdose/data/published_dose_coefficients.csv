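# Published cohort dose coefficients for the Ga-68-labeled exendin-4 beta-cell
# tracer (first-in-human PET dosimetry, n=6 adults): organ-absorbed doses in
# mGy/MBq and effective doses in mSv/MBq, mean and SD, for the reference adult
# models (pooled) and the newborn / 1-y / 5-y pediatric extrapolations.
# The adult spleen value follows the results text (0.011 +/- 0.001); the
# tabulated 0.001 is an apparent typo (SD equal to mean of neighbours' scale).
model,site,mean,sd,unit
adult,adrenals,0.012,0.002,mGy_per_MBq
adult,brain,0.005,0.0006,mGy_per_MBq
adult,breasts,0.005,0.0006,mGy_per_MBq
adult,gallbladder_wall,0.008,0.0008,mGy_per_MBq
adult,stomach_wall,0.007,0.0007,mGy_per_MBq
adult,heart_wall,0.006,0.0006,mGy_per_MBq
adult,kidneys,0.472,0.1019,mGy_per_MBq
adult,lower_large_intestine_wall,0.006,0.0007,mGy_per_MBq
adult,upper_large_intestine_wall,0.007,0.0007,mGy_per_MBq
adult,small_intestine,0.008,0.0010,mGy_per_MBq
adult,liver,0.008,0.0008,mGy_per_MBq
adult,lungs,0.006,0.0006,mGy_per_MBq
adult,muscle,0.006,0.0006,mGy_per_MBq
adult,ovaries,0.006,0.0008,mGy_per_MBq
adult,pancreas,0.023,0.0083,mGy_per_MBq
adult,red_marrow,0.006,0.0005,mGy_per_MBq
adult,osteogenic_cells,0.008,0.0010,mGy_per_MBq
adult,skin,0.005,0.0005,mGy_per_MBq
adult,spleen,0.011,0.001,mGy_per_MBq
adult,testes,0.002,0.0003,mGy_per_MBq
adult,thymus,0.005,0.0006,mGy_per_MBq
adult,thyroid,0.005,0.0006,mGy_per_MBq
adult,urinary_bladder_wall,0.005,0.0007,mGy_per_MBq
adult,uterus,0.004,0.0003,mGy_per_MBq
adult,total_body,0.008,0.0009,mGy_per_MBq
adult,effective_dose,0.0071,0.0007,mSv_per_MBq
newborn,kidneys,5.430,1.086,mGy_per_MBq
newborn,pancreas,0.530,0.217,mGy_per_MBq
newborn,adrenals,0.129,0.015,mGy_per_MBq
newborn,spleen,0.112,0.017,mGy_per_MBq
newborn,small_intestine,0.114,0.017,mGy_per_MBq
newborn,total_body,0.117,0.014,mGy_per_MBq
newborn,effective_dose,0.116,0.016,mSv_per_MBq
one_year,kidneys,2.037,0.408,mGy_per_MBq
one_year,pancreas,0.160,0.062,mGy_per_MBq
one_year,adrenals,0.059,0.007,mGy_per_MBq
one_year,spleen,0.050,0.006,mGy_per_MBq
one_year,small_intestine,0.047,0.007,mGy_per_MBq
one_year,total_body,0.046,0.006,mGy_per_MBq
one_year,effective_dose,0.038,0.005,mSv_per_MBq
five_year,kidneys,1.125,0.225,mGy_per_MBq
five_year,pancreas,0.082,0.021,mGy_per_MBq
five_year,adrenals,0.033,0.004,mGy_per_MBq
five_year,spleen,0.028,0.003,mGy_per_MBq
five_year,small_intestine,0.047,0.007,mGy_per_MBq
five_year,total_body,0.023,0.003,mGy_per_MBq
five_year,effective_dose,0.019,0.003,mSv_per_MBq
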