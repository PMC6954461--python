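patient_id,sex,age_y,weight_kg,injected_activity_mbq,scan1_min,scan2_min,scan3_min,scan4_min
1,F,24,72.0,106.1,32,66,121,239
2,F,53,58.0,107.5,32,62,120,238
3,F,55,75.6,108.0,30,83,119,235
4,M,65,83.6,105.0,30,61,120,234
5,F,64,88.8,105.1,30,56,115,235
6,M,63,84.5,101.6,30,62,118,236
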