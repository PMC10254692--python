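# Default bindings for the 14 PINCER measure keys (13 clinical indicators; the
# methotrexate indicator contributes two monitoring measures).  Codelist names
# refer to CSV files shipped alongside this file; all codes are synthetic
# stand-ins for the PRIMIS SNOMED-CT / dm+d content, which is configuration
# input rather than package data.
lookback_days: 90
indicators:
  a_age65_nsaid:
    group: gi_bleed
    min_age: 65
    codelists: {hazard: oral_nsaid, protective: ulcer_healing_drug}
  b_pu_nsaid:
    group: gi_bleed
    codelists: {condition: peptic_ulcer, hazard: oral_nsaid, protective: ulcer_healing_drug}
  c_pu_antiplatelet:
    group: gi_bleed
    codelists: {condition: peptic_ulcer, hazard: antiplatelet_any, protective: ulcer_healing_drug}
  d_anticoag_nsaid:
    group: gi_bleed
    codelists: {base_med: anticoagulant, hazard: oral_nsaid}
  e_anticoag_antiplatelet:
    group: gi_bleed
    codelists: {base_med: anticoagulant, hazard: antiplatelet_any, protective: ulcer_healing_drug}
  f_aspirin_antiplatelet:
    group: gi_bleed
    codelists: {base_med: aspirin, hazard: antiplatelet_other, protective: ulcer_healing_drug}
  g_hf_nsaid:
    group: cautioned
    codelists: {condition: heart_failure, hazard: oral_nsaid}
  h_asthma_betablocker:
    group: cautioned
    codelists: {condition: asthma, hazard: beta_blocker_nonselective}
  i_crf_nsaid:
    group: cautioned
    requires_numeric_values: true
    egfr_threshold: 45.0
    codelists: {threshold_test: egfr, hazard: oral_nsaid}
  j_acei_loop_no_renal:
    group: monitoring
    min_age: 75
    min_treatment_months: 3
    monitoring_window_months: 15
    codelists: {base_med: acei_or_loop, monitoring_test: renal_function}
  k_mtx_no_fbc:
    group: monitoring
    min_treatment_months: 3
    monitoring_window_months: 3
    codelists: {base_med: methotrexate, monitoring_test: full_blood_count}
  l_mtx_no_lft:
    group: monitoring
    min_treatment_months: 3
    monitoring_window_months: 3
    codelists: {base_med: methotrexate, monitoring_test: liver_function}
  m_lithium_no_level:
    group: monitoring
    min_treatment_months: 3
    monitoring_window_months: 3
    codelists: {base_med: lithium_medication, monitoring_test: lithium_level}
  n_amiodarone_no_tft:
    group: monitoring
    min_treatment_months: 6
    monitoring_window_months: 6
    codelists: {base_med: amiodarone, monitoring_test: thyroid_function}
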