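{
  "_comment": "Provenance of packaged exemplar rules. 'authored: true' marks cell values (temperature ranges, day cutoffs, probabilities) chosen by the package authors to satisfy the guideline-prose constraints; 'guideline_constraints' lists the constraints that are stated in the source clinical-guideline prose rather than authored.",
  "10301": {"file": "pci_guideline.csv", "row": 1, "authored": true, "guideline_constraints": ["pleural_wbc > 1000 (1e6/L)", "chest pain in progress note", "pleural effusion on imaging"]},
  "10302": {"file": "pci_guideline.csv", "row": 2, "authored": true, "guideline_constraints": ["pleural_wbc > 1000 (1e6/L)", "chest pain in progress note"]},
  "10303": {"file": "pci_guideline.csv", "row": 3, "authored": true, "guideline_constraints": ["bacteria observed in pleural effusion or smear confirms the diagnosis"]},
  "10304": {"file": "pci_guideline.csv", "row": 4, "authored": true, "guideline_constraints": ["etiologic confirmation plus full clinical picture"]},
  "20101": {"file": "uti_guideline.csv", "row": 1, "authored": true, "guideline_constraints": ["hospital-days gate separating hospital-acquired from community-acquired onset", "urinary symptoms in progress note", "urinary leukocyte abnormal flag"]},
  "20102": {"file": "uti_guideline.csv", "row": 2, "authored": true, "guideline_constraints": ["urinary fluid leukocyte number", "urinary bacteria count abnormal flag"]},
  "20103": {"file": "uti_guideline.csv", "row": 3, "authored": true, "guideline_constraints": ["clinical criteria without fever"]},
  "20104": {"file": "uti_guideline.csv", "row": 4, "authored": true, "guideline_constraints": ["etiologic criterion: positive urine culture"]},
  "90101": {"file": "lri_expert.csv", "row": 1, "authored": true, "expert_constraints": ["hospital day", "patient age", "presence of a PCT lab"]},
  "90102": {"file": "lri_expert.csv", "row": 2, "authored": true, "expert_constraints": ["presence of a PCT lab", "fever with productive cough"]},
  "90103": {"file": "lri_expert.csv", "row": 3, "authored": true, "expert_constraints": ["fever, productive cough and infiltrate on imaging"]},
  "90104": {"file": "lri_expert.csv", "row": 4, "authored": true, "expert_constraints": ["prolonged stay with PCT ordered and infiltrate on imaging"]}
}
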