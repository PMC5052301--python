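# Default synthetic-cohort specification.
#
# Calibrated to the published baseline wave of the Austrian audit cohort:
# 20 single-handed practices, per-indicator fulfilment dispersion given as
# (Q1, median, Q3) percentage triples that are quantile-matched to a Beta
# distribution on the probability scale, and disease prevalences of the
# observed order of magnitude.  Wave effects default to zero (no secular
# trend); tests and experiments override them.
n_gps: 20
waves:
  - label: "2012"
    reference_date: 2012-07-01
  - label: "2013"
    reference_date: 2013-05-01
  - label: "2014"
    reference_date: 2014-03-01
patients_per_practice:
  mean: 1400
  dispersion: 0.25      # lognormal sigma on the patient count
prevalence_pct:
  DM2: 3.9
  HT: 14.3
  CHD: 2.9
  CBVD: 1.3
  PAD: 0.6
  CHF: 0.6
  AF: 1.6
  COPD: 1.8
visit_coverage: 1.0
prevalence_only_fraction: 0.15   # fraction of practices whose EHR exports prevalences only
seed: 0
# Baseline fulfilment dispersion per scored indicator: Q1 / median / Q3 in %.
fulfilment:
  dm2_bmi:               {q1: 6.5,  median: 18.4, q3: 69.1}
  dm2_bp:                {q1: 33.0, median: 56.9, q3: 76.6}
  dm2_smoking:           {q1: 0.0,  median: 4.1,  q3: 9.7}
  dm2_creatinine:        {q1: 31.9, median: 46.8, q3: 72.5}
  dm2_hba1c_done:        {q1: 39.5, median: 55.4, q3: 77.4}
  dm2_hba1c_lt_7_5:      {q1: 31.1, median: 74.0, q3: 93.5}
  dm2_metformin_if_high: {q1: 19.8, median: 53.9, q3: 82.1}
  ht_bmi:                {q1: 6.2,  median: 16.3, q3: 53.1}
  ht_bp:                 {q1: 39.1, median: 50.6, q3: 75.3}
  ht_smoking:            {q1: 0.8,  median: 5.8,  q3: 11.2}
  ht_creatinine:         {q1: 18.5, median: 41.0, q3: 52.0}
  chd_bmi:               {q1: 6.5,  median: 24.4, q3: 51.7}
  chd_bp:                {q1: 44.8, median: 53.5, q3: 77.0}
  chd_smoking:           {q1: 0.0,  median: 4.6,  q3: 5.7}
  chd_statin:            {q1: 27.8, median: 36.9, q3: 48.7}
  chd_beta_blocker:      {q1: 22.8, median: 30.5, q3: 40.1}
  chd_antithrombotic:    {q1: 57.3, median: 69.7, q3: 75.9}
  cbvd_bmi:              {q1: 2.3,  median: 24.2, q3: 49.9}
  cbvd_bp:               {q1: 39.0, median: 52.3, q3: 73.3}
  cbvd_smoking:          {q1: 0.0,  median: 5.6,  q3: 11.1}
  cbvd_statin:           {q1: 17.3, median: 29.6, q3: 36.5}
  cbvd_antithrombotic:   {q1: 56.0, median: 65.0, q3: 71.1}
  pad_bmi:               {q1: 7.7,  median: 25.0, q3: 52.3}
  pad_bp:                {q1: 32.5, median: 47.2, q3: 77.1}
  pad_smoking:           {q1: 0.0,  median: 0.0,  q3: 20.0}
  pad_statin:            {q1: 19.0, median: 34.0, q3: 50.0}
  pad_antithrombotic:    {q1: 63.5, median: 74.2, q3: 80.3}
  chf_bmi:               {q1: 0.0,  median: 20.0, q3: 57.6}
  chf_bp:                {q1: 26.9, median: 60.0, q3: 86.4}
  chf_ace_arb:           {q1: 18.7, median: 43.8, q3: 60.5}
  chf_beta_blocker:      {q1: 9.8,  median: 29.4, q3: 48.5}
  af_bp:                 {q1: 38.7, median: 57.5, q3: 76.2}
  af_antithrombotic:     {q1: 58.5, median: 67.8, q3: 76.3}
  copd_smoking:          {q1: 2.7,  median: 13.1, q3: 39.6}
  copd_spirometry:       {q1: 3.7,  median: 11.7, q3: 17.7}
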