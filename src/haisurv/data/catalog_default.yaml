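# Infection catalog: 12 infection sites, 40 infection diagnoses.
# Codes are the uppercase abbreviations used throughout the rule base;
# full names are display strings only.
sites:
  - code: RTI
    name: Respiratory tract infection
    diagnoses:
      - {code: UR, name: Upper respiratory tract infection}
      - {code: LRI, name: Lower respiratory tract infection}
      - {code: PCI, name: Pleural cavity infection}
      - {code: VAP, name: Ventilator-associated pneumonia}
  - code: CVS
    name: Cardiovascular system infection
    diagnoses:
      - {code: ENDO, name: Endocarditis}
      - {code: CARD, name: Myocarditis or pericarditis}
  - code: BSI
    name: Bloodstream infection
    diagnoses:
      - {code: VAI, name: Vascular associated infection}
      - {code: SEP, name: Septicemia}
      - {code: TRN-BSI, name: Transfusion-related infection}
  - code: AD/GI
    name: Abdomen / gastrointestinal system infection
    diagnoses:
      - {code: ID, name: Infectious diarrhea}
      - {code: GIT, name: Gastrointestinal tract infection}
      - {code: ADT, name: Antimicrobial drug-related diarrhea}
      - {code: VHS, name: Viral hepatitis}
      - {code: IAB, name: Intraabdominal infection, not specified elsewhere}
      - {code: PFIT, name: Peritoneal fluid infection}
  - code: CNS
    name: Central nervous system infection
    diagnoses:
      - {code: MEN, name: Meningitis or ventriculitis}
      - {code: IC, name: Intracranial infection}
      - {code: SA, name: Spinal abscess/infection}
  - code: USI
    name: Urinary system infection
    diagnoses:
      - {code: UTI, name: Non-catheter-associated urinary tract infection}
      - {code: CAUTI, name: Catheter-associated urinary tract infection}
  - code: SSI
    name: Surgical site infection
    diagnoses:
      - {code: SI-SSI, name: Superficial incisional SSI}
      - {code: DI-SSI, name: Deep incisional SSI}
      - {code: OS-SSI, name: Organ/space SSI}
  - code: BJ
    name: Bone and joint infection
    diagnoses:
      - {code: JNT, name: Joint or bursa infection}
      - {code: OST, name: Osteomyelitis}
      - {code: DSI, name: Disc space infection}
  - code: SST
    name: Skin and soft tissue infection
    diagnoses:
      - {code: SKIN, name: Skin infection}
      - {code: ST, name: Soft tissue infection}
      - {code: DECU, name: Decubitus ulcer infection}
      - {code: BURN, name: Burn infection}
      - {code: BRST, name: Breast infection or mastitis}
      - {code: UMB, name: Omphalitis}
      - {code: IP, name: Infant pustulosis}
  - code: REPR
    name: Reproductive tract infection
    diagnoses:
      - {code: EPIS, name: Episiotomy infection}
      - {code: VCUF, name: Vaginal cuff infection}
      - {code: PLI, name: Pelvic infection}
      - {code: EMET, name: Endometritis}
      - {code: OTH-REPR, name: Other infections of reproductive tract}
  - code: ORAL
    name: Oral cavity infection
    diagnoses:
      - {code: ORAL, name: Oral cavity infection}
  - code: OTH
    name: Other
    diagnoses:
      - {code: OTH, name: Other infections could not be confirmed}
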