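{
  "name": "LOCAL",
  "description": "Locally-maintained engine parameterization: diabetes asserted from problem list, hypoglycemic medications, or ICD9 discharge diagnoses; gestational diabetes not excluded; angina not counted as CAD; no renal-disease exclusion on microalbumin screening; unbounded microalbuminuria evidence window; blindness and recent eye-clinic-visit exclusions on the eye-exam reminder; broad blood-pressure code set; narrow contraindication sets.",
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
    "BP_LAB": ["BP_SYSTOLIC", "BP_SYSTOLIC_SITTING"],
    "EYE_EXAM": ["EYE_EXAM"],
    "FOOT_EXAM": ["FOOT_EXAM"],
    "BLINDNESS": ["BLINDNESS"],
    "EYE_CLINIC_VISIT": ["EYE_CLINIC_VISIT"],
    "ACE_I": ["ACE_I"],
    "ARB": ["ARB"],
    "ANTIPLATELET": ["ANTIPLATELET"],
    "ORAL_HYPOGLYCEMIC": ["ORAL_HYPOGLYCEMIC"],
    "INSULIN": ["INSULIN"],
    "ACE_CONTRA": ["ACE_ALLERGY"],
    "ARB_CONTRA": ["ARB_ALLERGY"],
    "ANTIPLATELET_CONTRA": ["BLEEDING_DISORDER", "THROMBOCYTOPENIA", "GI_BLEED"]
  },
  "diabetes_sources": ["problem_list", "hypoglycemic_meds", "icd9_discharge"],
  "exclude_gestational_diabetes": false,
  "angina_implies_cad": false,
  "microalbumin_excludes_renal_disease": false,
  "ace_evidence_lookback_months": null,
  "eye_exam_exclusions": ["blindness", "eye_clinic_visit_within_12mo"],
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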