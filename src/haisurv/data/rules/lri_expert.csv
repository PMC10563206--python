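RuleSet,lri_expert
Diagnosis,LRI
Source,expert
CONDITION,CONDITION,CONDITION,CONDITION,CONDITION,CONDITION,ACTION,ACTION
hospital_days ge,age ge,has_pct_lab eq,body_temperature_max in_range,cough_sputum eq,lung_infiltrate_imaging eq,rule_id,probability
3,65,1,38.0..41.0,,,90101,0.50
3,,1,38.0..41.0,1,,90102,0.55
3,,,38.0..41.0,1,1,90103,0.60
5,,1,,,1,90104,0.55
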