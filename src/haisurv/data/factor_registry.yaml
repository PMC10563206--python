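# Declarative registry of infection factors.
# Each factor belongs to exactly one case-tuple group:
#   DE demographics, PS hospitalization status, PN progress-note flags,
#   IR imaging-report flags, VS vital signs, CL clinical laboratory,
#   OP operations, MO medical orders.
# kind: integer | real | date | binary.  Unknown factors encountered in a
# case are a validation issue, never a crash.
factors:
  # --- demographics -------------------------------------------------------
  - {id: age, kind: integer, unit: years, group: DE, description: Patient age at admission}
  - {id: gender, kind: binary, unit: "", group: DE, description: "Patient gender (0 female, 1 male)"}
  # --- hospitalization status --------------------------------------------
  - {id: admission_datetime, kind: date, unit: "", group: PS, description: Admission timestamp}
  - {id: hospital_days, kind: integer, unit: days, group: PS, description: Calendar hospital day (admission day = 1)}
  # --- vital signs --------------------------------------------------------
  - {id: body_temperature_max, kind: real, unit: degC, group: VS, description: Highest body temperature of the surveillance day}
  - {id: defecation_frequency, kind: integer, unit: per_day, group: VS, description: Number of bowel movements on the surveillance day}
  # --- clinical laboratory ------------------------------------------------
  - {id: pct, kind: real, unit: ng/mL, group: CL, description: Latest procalcitonin result on or before the day}
  - {id: has_pct_lab, kind: binary, unit: "", group: CL, description: Whether the patient has any PCT lab result}
  - {id: crp, kind: real, unit: mg/L, group: CL, description: Latest C-reactive protein result}
  - {id: blood_wbc, kind: real, unit: 1e9/L, group: CL, description: Latest blood leukocyte count}
  - {id: urine_wbc, kind: real, unit: 1e6/L, group: CL, description: Latest urinary fluid leukocyte number}
  - {id: urine_wbc_abnormal, kind: binary, unit: "", group: CL, description: Urinary fluid leukocyte abnormal flag}
  - {id: urine_bacteria_abnormal, kind: binary, unit: "", group: CL, description: Urinary bacteria count abnormal flag}
  - {id: pleural_wbc, kind: real, unit: 1e6/L, group: CL, description: Latest pleural effusion fluid leukocyte count}
  - {id: urine_culture_positive, kind: binary, unit: "", group: CL, description: Positive urine culture on or before the day}
  - {id: pleural_culture_positive, kind: binary, unit: "", group: CL, description: Positive pleural fluid culture / smear}
  - {id: blood_culture_positive, kind: binary, unit: "", group: CL, description: Positive blood culture}
  - {id: sputum_culture_positive, kind: binary, unit: "", group: CL, description: Positive sputum culture}
  # --- progress-note keyword flags ---------------------------------------
  - {id: chest_pain, kind: binary, unit: "", group: PN, description: Chest pain mentioned in progress notes}
  - {id: urinary_symptoms, kind: binary, unit: "", group: PN, description: Frequent/urgent/painful urination mentioned in progress notes}
  - {id: cough_sputum, kind: binary, unit: "", group: PN, description: Productive cough / purulent sputum mentioned in progress notes}
  - {id: purulent_effusion, kind: binary, unit: "", group: PN, description: Purulent or foul-smelling pleural effusion mentioned in notes}
  # --- imaging-report keyword flags --------------------------------------
  - {id: pleural_effusion_imaging, kind: binary, unit: "", group: IR, description: Pleural effusion reported on imaging}
  - {id: lung_infiltrate_imaging, kind: binary, unit: "", group: IR, description: New pulmonary infiltrate / consolidation on imaging}
  # --- operations ---------------------------------------------------------
  - {id: recent_operation, kind: binary, unit: "", group: OP, description: Any operation during the episode on or before the day}
  # --- medical orders -----------------------------------------------------
  - {id: urinary_catheter, kind: binary, unit: "", group: MO, description: Urinary catheter order active on the day}
  - {id: ventilator, kind: binary, unit: "", group: MO, description: Ventilator order active on the day}
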