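indicator_id,median_pct
dm2_bmi,18.4
dm2_bp,56.9
dm2_smoking,4.1
dm2_creatinine,46.8
dm2_hba1c_done,55.4
dm2_hba1c_lt_7_5,74.0
dm2_metformin_if_high,53.8
ht_bmi,16.3
ht_bp,50.6
ht_smoking,5.8
ht_creatinine,41.0
chd_bmi,24.4
chd_bp,53.5
chd_smoking,4.5
chd_statin,36.9
chd_beta_blocker,30.5
chd_antithrombotic,69.7
cbvd_bmi,24.2
cbvd_bp,52.3
cbvd_smoking,5.6
cbvd_statin,29.6
cbvd_antithrombotic,65.0
pad_bmi,25.0
pad_bp,47.2
pad_smoking,0.0
pad_statin,34.0
pad_antithrombotic,74.2
chf_bmi,20.0
chf_bp,60.0
chf_ace_arb,43.8
chf_beta_blocker,29.4
af_bp,57.5
af_antithrombotic,67.8
copd_smoking,13.1
copd_spirometry,11.7
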