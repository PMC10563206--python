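# Keyword lexicon for text-derived binary factors.
# Matching is substring-based on case-folded, whitespace-normalized text;
# a hit is discarded when the matched sentence contains a negation cue.
# English defaults; the lexicon format is language-agnostic.
negation_cues_default: ["no ", "denies", "without", "absence of", "negative for"]
entries:
  - factor_id: chest_pain
    note_type: progress
    keywords: ["chest pain", "pleuritic pain"]
  - factor_id: urinary_symptoms
    note_type: progress
    keywords: ["frequent urination", "urgent urination", "dysuria", "painful urination"]
  - factor_id: cough_sputum
    note_type: progress
    keywords: ["productive cough", "purulent sputum", "coughing up sputum"]
  - factor_id: purulent_effusion
    note_type: progress
    keywords: ["purulent pleural effusion", "foul-smelling effusion", "purulent effusion"]
  - factor_id: pleural_effusion_imaging
    note_type: imaging
    keywords: ["pleural effusion"]
  - factor_id: lung_infiltrate_imaging
    note_type: imaging
    keywords: ["pulmonary infiltrate", "new infiltrate", "consolidation"]
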