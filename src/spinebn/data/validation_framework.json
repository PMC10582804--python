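[
  {
    "domain": "nomological",
    "question": "Does the model fit within an appropriate context in the literature?",
    "method": "Containment check of the structure against published red-flag factor lists",
    "implemented": true
  },
  {
    "domain": "face",
    "question": "Does the model structure look the same as experts of the literature predict?",
    "method": "Independent expert review, summarized with chance-corrected agreement",
    "implemented": true
  },
  {
    "domain": "content",
    "question": "Does the model structure contain all and only the factors and relationships relevant to the output?",
    "method": "Independent expert review scored with Gwet AC2 and Landis-Koch bands",
    "implemented": true
  },
  {
    "domain": "predictive",
    "question": "Is the model behavior predictive of the system being modeled?",
    "method": "Labeled patient cases scored by posterior probability; ROC/AUC per condition",
    "implemented": true
  },
  {
    "domain": "concurrent",
    "question": "Does the model act identically to a network modeling a theoretically related construct?",
    "method": "Requires a comparator model; deferred",
    "implemented": false
  },
  {
    "domain": "convergent",
    "question": "How similar is the model structure to nomologically proximal models?",
    "method": "Requires a comparator model; deferred",
    "implemented": false
  },
  {
    "domain": "discriminant",
    "question": "How different is the model structure from nomologically distant models?",
    "method": "Requires a comparator model; deferred",
    "implemented": false
  }
]
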