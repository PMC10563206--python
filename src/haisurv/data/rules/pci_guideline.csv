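RuleSet,pci_guideline
Diagnosis,PCI
Source,guideline
CONDITION,CONDITION,CONDITION,CONDITION,CONDITION,ACTION,ACTION
body_temperature_max in_range,chest_pain eq,pleural_effusion_imaging eq,pleural_wbc gt,pleural_culture_positive eq,rule_id,probability
38.0..41.0,1,1,1000,,10301,0.60
38.0..41.0,1,,1000,,10302,0.50
,,1,,1,10303,0.90
38.0..41.0,,1,1000,1,10304,0.95
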