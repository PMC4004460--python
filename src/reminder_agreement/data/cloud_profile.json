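{
  "name": "CLOUD",
  "description": "Consortium-maintained engine parameterization: problem-list-only diabetes excluding gestational diabetes, angina counted as CAD, renal-disease exclusion on microalbumin screening, 12-month microalbuminuria evidence window for ACE advice, no eye-exam exclusions, narrow blood-pressure code set, extended contraindication sets.",
  "concept_sets": {
    "DIABETES": ["DIABETES", "GESTATIONAL_DIABETES"],
    "GESTATIONAL_DIABETES": ["GESTATIONAL_DIABETES"],
    "DIABETES_ICD9": ["DIABETES_ICD9"],
    "RENAL_DISEASE": ["RENAL_DISEASE"],
    "ESRD": ["ESRD"],
    "CAD": ["CAD"],
    "ANGINA": ["ANGINA"],
    "HBA1C_LAB": ["HBA1C_LAB"],
    "MICROALBUMIN_LAB": ["MICROALBUMIN_LAB"],
    "BP_LAB": ["BP_SYSTOLIC"],
    "EYE_EXAM": ["EYE_EXAM"],
    "FOOT_EXAM": ["FOOT_EXAM"],
    "BLINDNESS": ["BLINDNESS"],
    "EYE_CLINIC_VISIT": ["EYE_CLINIC_VISIT"],
    "ACE_I": ["ACE_I"],
    "ARB": ["ARB"],
    "ANTIPLATELET": ["ANTIPLATELET"],
    "ORAL_HYPOGLYCEMIC": ["ORAL_HYPOGLYCEMIC"],
    "INSULIN": ["INSULIN"],
    "ACE_CONTRA": ["ACE_ALLERGY", "PREGNANCY", "HYPERKALEMIA"],
    "ARB_CONTRA": ["ARB_ALLERGY"],
    "ANTIPLATELET_CONTRA": ["BLEEDING_DISORDER", "THROMBOCYTOPENIA", "GI_BLEED", "ESOPHAGEAL_VARICES", "COAG_FACTOR_DEFICIENCY", "CEREBRAL_HEMORRHAGE"]
  },
  "diabetes_sources": ["problem_list"],
  "exclude_gestational_diabetes": true,
  "angina_implies_cad": true,
  "microalbumin_excludes_renal_disease": true,
  "ace_evidence_lookback_months": 12,
  "eye_exam_exclusions": [],
  "windows": {
    "hba1c_due": 6,
    "hba1c_almost_due_lo": 5,
    "hba1c_poor_lo": 3,
    "hba1c_poor_hi": 5,
    "hba1c_poor_threshold": 8.0,
    "microalbumin_lookback": 11,
    "eye_exam_lookback": 11,
    "foot_exam_lookback": 11,
    "bp_lookback": 12
  }
}
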