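# Canonical cohort-file schema (CSV, UTF-8, header row, configurable
# delimiter).  Blank cells mean "unknown" — never zero or false.
# Tri-state columns accept 1/0/"", yes/no, true/false, present/absent,
# high/low (rater columns).  Units are fixed; no auto-detection.
#
# Files may use different headers via a {file_header: canonical} alias
# map passed to the reader.

mandatory:
  id:        {type: string, doc: unique participant identifier}
  country:   {type: string, doc: "recruitment country (study strata: UK, Germany, Portugal, Spain, Greece; extensible)"}
  sex:       {type: enum, values: [male, female]}
  age_years: {type: integer, values: [12, 13, 14], doc: completed years}

numeric:   # blank -> unknown; strictly positive when known
  bmi:                             {unit: kg/m2}
  bmi_z:                           {unit: SD score, doc: BMI z-score against an age/sex growth reference; 1.04 = 85th percentile}
  waist_cm:                        {unit: cm}
  screen_hours_per_day:            {unit: hours}
  physical_activity_min_per_day:   {unit: minutes}
  fruit_veg_portions_per_day:      {unit: portions}
  sugary_drink_ml_per_day:         {unit: ml}
  infant_weight_gain_g_per_month:  {unit: g/month, doc: weight-gain rate in infancy}
  parent1_bmi:                     {unit: kg/m2}
  parent2_bmi:                     {unit: kg/m2}
  glucose_mmol_l:                  {unit: mmol/L}
  hba1c_pct:                       {unit: "%"}
  total_chol_mmol_l:               {unit: mmol/L}
  ldl_mmol_l:                      {unit: mmol/L}
  triglycerides_mmol_l:            {unit: mmol/L}

blood_pressure:   # up to three readings; trailing blanks = fewer readings
  systolic1:  {unit: mmHg}
  diastolic1: {unit: mmHg}
  systolic2:  {unit: mmHg}
  diastolic2: {unit: mmHg}
  systolic3:  {unit: mmHg}
  diastolic3: {unit: mmHg}

tristate:   # 1 / 0 / blank
  breast_fed: {doc: ever fed on breast milk}
  first_degree_fh_diabetes: {}
  second_degree_fh_diabetes: {}
  ethnicity_caucasian: {}
  acanthosis_nigricans: {}
  fatty_liver: {}
  pcos: {}
  prediabetes_flag: {doc: explicit clinician pre-diabetes flag (otherwise derived from HbA1c)}
  sga_flag: {doc: small for gestational age}
  parent1_white_european: {}
  parent2_white_european: {}
  fasting: {doc: whether the blood sample was fasting}
  rater1_high: {doc: first clinician lifetime-risk judgement}
  rater2_high: {doc: second clinician lifetime-risk judgement}
  rater3_high: {doc: tiebreak clinician judgement (blank unless needed)}
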