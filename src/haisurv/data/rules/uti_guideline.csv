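RuleSet,uti_guideline
Diagnosis,UTI
Source,guideline
CONDITION,CONDITION,CONDITION,CONDITION,CONDITION,CONDITION,CONDITION,ACTION,ACTION
body_temperature_max in_range,hospital_days ge,urine_wbc gt,urine_wbc_abnormal eq,urine_bacteria_abnormal eq,urinary_symptoms eq,urine_culture_positive eq,rule_id,probability
38.0..41.0,3,,1,,1,,20101,0.50
38.0..41.0,3,10,,1,,,20102,0.55
,3,,1,1,1,,20103,0.60
,3,,,,,1,20104,0.90
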