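[
  {"baseline": "Low-risk CES", "condition": "cauda_equina_syndrome", "source": "consensus literature", "variations": ["higher_risk", "add_cancer_symptoms", "add_inflammatory_symptoms"]},
  {"baseline": "Low- to midrisk CES", "condition": "cauda_equina_syndrome", "source": "consensus literature", "variations": ["higher_risk", "add_cancer_symptoms", "add_inflammatory_symptoms"]},
  {"baseline": "Midrisk CES", "condition": "cauda_equina_syndrome", "source": "consensus literature", "variations": ["higher_risk", "add_cancer_symptoms", "add_inflammatory_symptoms"]},
  {"baseline": "High-risk CES", "condition": "cauda_equina_syndrome", "source": "consensus literature", "variations": ["higher_risk", "add_cancer_symptoms", "add_inflammatory_symptoms"]},
  {"baseline": "Low-risk fracture", "condition": "fracture", "source": "consensus literature", "variations": ["higher_risk", "add_cancer_symptoms", "add_inflammatory_symptoms"]},
  {"baseline": "Low- to midrisk fracture", "condition": "fracture", "source": "consensus literature", "variations": ["higher_risk", "add_cancer_symptoms", "add_inflammatory_symptoms"]},
  {"baseline": "Midrisk fracture", "condition": "fracture", "source": "consensus literature", "variations": ["higher_risk", "add_cancer_symptoms", "add_inflammatory_symptoms"]},
  {"baseline": "High-risk fracture", "condition": "fracture", "source": "consensus literature", "variations": ["higher_risk", "add_cancer_symptoms", "add_inflammatory_symptoms"]},
  {"baseline": "Low-risk malignancy", "condition": "space_occupying_lesion", "source": "consensus literature", "variations": ["higher_risk", "add_inflammatory_symptoms"]},
  {"baseline": "Low- to midrisk malignancy", "condition": "space_occupying_lesion", "source": "consensus literature", "variations": ["higher_risk", "add_inflammatory_symptoms"]},
  {"baseline": "Midrisk malignancy", "condition": "space_occupying_lesion", "source": "consensus literature", "variations": ["higher_risk", "add_inflammatory_symptoms"]},
  {"baseline": "High-risk malignancy", "condition": "space_occupying_lesion", "source": "consensus literature", "variations": ["higher_risk", "add_inflammatory_symptoms"]},
  {"baseline": "Low-risk infection", "condition": "infective_condition", "source": "consensus literature", "variations": ["higher_risk", "add_cancer_symptoms", "add_inflammatory_symptoms"]},
  {"baseline": "Low- to midrisk infection", "condition": "infective_condition", "source": "consensus literature", "variations": ["higher_risk", "add_cancer_symptoms", "add_inflammatory_symptoms"]},
  {"baseline": "Midrisk infection", "condition": "infective_condition", "source": "consensus literature", "variations": ["higher_risk", "add_cancer_symptoms", "add_inflammatory_symptoms"]},
  {"baseline": "High-risk infection", "condition": "infective_condition", "source": "consensus literature", "variations": ["higher_risk", "add_cancer_symptoms", "add_inflammatory_symptoms"]},
  {"baseline": "Inflammatory condition (1)", "condition": "inflammatory_condition", "source": "real case", "variations": ["higher_risk", "add_cancer_symptoms"]},
  {"baseline": "Inflammatory condition (2)", "condition": "inflammatory_condition", "source": "real case", "variations": ["higher_risk", "add_cancer_symptoms"]},
  {"baseline": "Nerve root condition", "condition": "nerve_root_condition", "source": "case-study literature", "variations": ["higher_risk", "add_cancer_symptoms", "add_inflammatory_symptoms"]}
]
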