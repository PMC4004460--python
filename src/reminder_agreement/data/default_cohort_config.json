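{
  "n_visits": 405,
  "seed": 0,
  "p_diabetes": 0.45,
  "p_gestational_only": 0.03,
  "p_cad": 0.18,
  "p_angina_without_cad": 0.03,
  "p_renal": 0.15,
  "p_esrd_given_renal": 0.15,
  "p_on_ace": 0.30,
  "p_on_arb": 0.10,
  "p_on_antiplatelet": 0.35,
  "p_hypoglycemic_med_without_problem": 0.05,
  "p_hba1c": 0.80,
  "p_microalbumin": 0.55,
  "p_bp": 0.90,
  "p_eye_exam": 0.60,
  "p_foot_exam": 0.55,
  "lab_recency_max_months": 24.0,
  "hba1c_mean": 7.5,
  "hba1c_sd": 1.5,
  "p_bp_sitting_code": 0.55,
  "p_ace_contra": 0.06,
  "p_antiplatelet_contra_core": 0.04,
  "p_antiplatelet_contra_extended_only": 0.04,
  "p_blindness": 0.02,
  "p_eye_clinic_visit": 0.10
}
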