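set_name,system,code,display
DIABETES,SNOMED,901000001,Diabetes mellitus (synthetic placeholder code)
DIABETES,SNOMED,901000002,Type 2 diabetes mellitus (synthetic placeholder code)
GESTATIONAL_DIABETES,SNOMED,901000003,Gestational diabetes mellitus (synthetic placeholder code)
DIABETES_ICD9,ICD9,250.00,Diabetes mellitus without complication (synthetic placeholder code)
DIABETES_ICD9,ICD9,250.02,Diabetes mellitus type II uncontrolled (synthetic placeholder code)
RENAL_DISEASE,SNOMED,901000010,Chronic kidney disease (synthetic placeholder code)
RENAL_DISEASE,SNOMED,901000011,Diabetic nephropathy (synthetic placeholder code)
ESRD,SNOMED,901000012,End-stage renal disease (synthetic placeholder code)
CAD,SNOMED,901000020,Coronary artery disease (synthetic placeholder code)
CAD,SNOMED,901000021,Old myocardial infarction (synthetic placeholder code)
ANGINA,SNOMED,194828000,Angina
HBA1C_LAB,LOINC,99901-1,Hemoglobin A1c (synthetic placeholder code)
MICROALBUMIN_LAB,LOINC,99902-9,Microalbumin/creatinine ratio in urine (synthetic placeholder code)
BP_SYSTOLIC,LOINC,8480-6,Systolic blood pressure
BP_SYSTOLIC_SITTING,LOINC,8459-0,Systolic blood pressure - sitting
EYE_EXAM,LOCAL,EYE-EXAM,Ophthalmologic exam documented (synthetic placeholder code)
FOOT_EXAM,LOCAL,FOOT-EXAM,Foot exam documented (synthetic placeholder code)
EYE_CLINIC_VISIT,LOCAL,EYE-CLINIC,Eye clinic visit (synthetic placeholder code)
BLINDNESS,SNOMED,901000030,Blindness (synthetic placeholder code)
ACE_I,MEDCLASS,ACE_I,ACE inhibitor class
ARB,MEDCLASS,ARB,Angiotensin-2 receptor blocker class
ANTIPLATELET,MEDCLASS,ANTIPLATELET,Antiplatelet class
ORAL_HYPOGLYCEMIC,MEDCLASS,ORAL_HYPOGLYCEMIC,Oral hypoglycemic class
INSULIN,MEDCLASS,INSULIN,Insulin class
ACE_ALLERGY,SNOMED,901000040,Allergy to ACE inhibitor (synthetic placeholder code)
PREGNANCY,SNOMED,901000041,Pregnancy (synthetic placeholder code)
HYPERKALEMIA,SNOMED,901000042,Hyperkalemia (synthetic placeholder code)
ARB_ALLERGY,SNOMED,901000043,Allergy to ARB (synthetic placeholder code)
BLEEDING_DISORDER,SNOMED,901000050,Bleeding disorder (synthetic placeholder code)
THROMBOCYTOPENIA,SNOMED,901000051,Thrombocytopenia (synthetic placeholder code)
GI_BLEED,SNOMED,901000052,Gastrointestinal hemorrhage (synthetic placeholder code)
ESOPHAGEAL_VARICES,SNOMED,901000053,Esophageal varices (synthetic placeholder code)
COAG_FACTOR_DEFICIENCY,SNOMED,901000054,Coagulation factor deficiency syndrome (synthetic placeholder code)
CEREBRAL_HEMORRHAGE,SNOMED,901000055,Cerebral hemorrhage (synthetic placeholder code)
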