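{
  "cauda_equina_syndrome": [
    {"factor": "Unilateral radicular pain", "node": null, "type": "sign"},
    {"factor": "Bilateral radicular pain", "node": "bilateral_radicular_pain", "type": "sign"},
    {"factor": "Dermatomal reduced sensation", "node": null, "type": "sign"},
    {"factor": "Myotomal weakness", "node": "myotomal_weakness", "type": "sign"},
    {"factor": "Changes to bladder function", "node": "bladder_function_change", "type": "sign"},
    {"factor": "Changes to bowel function", "node": "bowel_function_change", "type": "sign"},
    {"factor": "Saddle sensory disturbance", "node": "saddle_sensory_disturbance", "type": "sign"}
  ],
  "space_occupying_lesion": [
    {"factor": "History of cancer", "node": "history_of_cancer", "type": "risk"},
    {"factor": "Night pain", "node": "night_pain", "type": "sign"},
    {"factor": "Requiring strong pain killers", "node": "requiring_strong_painkillers", "type": "sign"},
    {"factor": "Weight loss", "node": "weight_loss", "type": "sign"},
    {"factor": "Balance issues", "node": null, "type": "sign"},
    {"factor": "Odd sensations in legs", "node": "odd_sensations_in_legs", "type": "sign"}
  ],
  "fracture": [
    {"factor": "History of cancer", "node": "history_of_cancer", "type": "risk"},
    {"factor": "Multiple myeloma", "node": null, "type": "risk"},
    {"factor": "Osteoporosis", "node": "bone_health", "type": "risk"},
    {"factor": "Severe pain or worsening pain", "node": null, "type": "sign"},
    {"factor": "Age", "node": "age", "type": "risk"},
    {"factor": "Sex", "node": null, "type": "risk"},
    {"factor": "Smoker", "node": null, "type": "risk"},
    {"factor": "Pain worse when lying supine", "node": null, "type": "sign"},
    {"factor": "Early menopause or late menarche", "node": null, "type": "risk"},
    {"factor": "History of fracture", "node": null, "type": "risk"}
  ],
  "infective_condition": [
    {"factor": "Immunosuppression", "node": "immunosuppression", "type": "risk"},
    {"factor": "Steroid use", "node": "steroids", "type": "risk"},
    {"factor": "Smoking", "node": null, "type": "risk"},
    {"factor": "Obesity", "node": null, "type": "risk"},
    {"factor": "History of TB", "node": "history_of_tb", "type": "risk"},
    {"factor": "Fever", "node": "fever", "type": "sign"},
    {"factor": "Neurological dysfunction", "node": "neurological_dysfunction", "type": "sign"},
    {"factor": "User of intravenous drugs", "node": "intravenous_drug_use", "type": "risk"},
    {"factor": "Night pain", "node": "night_pain", "type": "sign"}
  ],
  "inflammatory_condition": [
    {"factor": "Age", "node": "age", "type": "risk"},
    {"factor": "Waking at night", "node": "sleep_disturbance", "type": "sign"},
    {"factor": "Improvement with movement", "node": null, "type": "sign"},
    {"factor": "Improvement with NSAIDs", "node": "nsaid_improvement", "type": "sign"},
    {"factor": "Past enthesitis, psoriasis, or arthritis", "node": "past_enthesitis_psoriasis_arthritis", "type": "risk"},
    {"factor": "Family history", "node": null, "type": "risk"},
    {"factor": "Uveitis", "node": "uveitis_or_ibd", "type": "risk"},
    {"factor": "Inflammatory bowel disease", "node": "uveitis_or_ibd", "type": "risk"}
  ],
  "nerve_root_condition": [
    {"factor": "Unilateral leg pain", "node": null, "type": "sign"},
    {"factor": "Dermatomal changes", "node": null, "type": "sign"},
    {"factor": "Myotomal weakness", "node": "myotomal_weakness", "type": "sign"},
    {"factor": "Straight leg raise test positive", "node": null, "type": "sign"},
    {"factor": "Age", "node": "age", "type": "risk"},
    {"factor": "Smoking", "node": null, "type": "risk"},
    {"factor": "Obesity", "node": null, "type": "risk"}
  ]
}
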