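{
  "space_occupying_lesion": 1.0,
  "cauda_equina_syndrome": 0.85,
  "infective_condition": 0.86,
  "fracture": 0.34,
  "cord_compression": 1.0,
  "inflammatory_condition": 0.91,
  "nerve_root_condition": 0.93,
  "irritability_of_pain": 0.68,
  "depression": 1.0,
  "stress": 1.0,
  "anxiety": 0.95
}
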