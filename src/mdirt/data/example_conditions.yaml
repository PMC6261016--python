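# Synthetic example condition dictionary (ICD-9 code-family patterns).
# Illustrates the dictionary format; these are NOT the code lists of any
# published comorbidity instrument.
- name: hypertension
  code_patterns: ["401.*", "402.*"]
  notes: essential and hypertensive heart disease families
- name: diabetes
  code_patterns: ["250.*"]
  notes: diabetes mellitus family
- name: depression
  code_patterns: ["296.2*", "296.3*", "311"]
  notes: major depressive episodes plus depressive disorder NEC
- name: alcohol_abuse
  code_patterns: ["303.*", "305.0*"]
  notes: dependence and non-dependent abuse
- name: drug_abuse
  code_patterns: ["304.*", "305.9*"]
  notes: dependence and unspecified non-dependent abuse
- name: liver_disease
  code_patterns: ["571.*"]
  notes: chronic liver disease and cirrhosis
- name: chronic_hepatitis
  code_patterns: ["070.3*", "571.4*"]
  notes: viral hepatitis B and chronic hepatitis
- name: congestive_heart_failure
  code_patterns: ["428.*"]
  notes: heart failure family
- name: coronary_artery_disease
  code_patterns: ["414.*"]
  notes: chronic ischemic heart disease
- name: obesity
  code_patterns: ["278.0*", "V85.*"]
  notes: includes BMI V-codes
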