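# spinebn

Serious spinal pathologies (SSPs) — cauda equina syndrome, spinal
malignancy, spinal infection, vertebral fracture, inflammatory disease —
are rare but devastating causes of low back pain, and the conventional
"red flag" checklist used to screen for them has poor validity. `spinebn`
implements an expert-elicited **causal Bayesian network** for this
screening problem, together with the mathematics used to build such a
model from a clinical panel and the instruments used to validate it. It
is aimed at researchers in clinical decision support and probabilistic
modelling who want a complete, testable reference pipeline: structure →
parameters → inference → validation.

## What is inside

- **Structure** (`spinebn.network`): a packaged three-layer DAG of 38
  binary variables — 10 risk factors → 11 judgment factors (the candidate
  pathologies) → 17 signs and symptoms — with per-element provenance tags
  and structural validation.
- **Parameters** (`spinebn.parameters`): root priors plus leaky noisy-OR
  conditional tables,
  `P(effect | causes A) = 1 − (1−λ)∏_{i∈A}(1−s_i)`,
  one link strength per edge plus a leak; seeded synthetic parameter sets
  with calibrated-rare pathology baselines.
- **Inference** (`spinebn.inference`): exact posteriors by variable
  elimination (min-fill ordering); unknown findings are simply omitted
  from the evidence and marginalized; a full-joint enumeration oracle
  backs the equivalence tests.
- **Consensus** (`spinebn.consensus`): the panel-aggregation mathematics
  used during elicitation — median scores, 30th–70th interpercentile
  range, include/exclude edge decisions, median-rank aggregation.
- **Validation** (`spinebn.validation`): Gwet AC2 chance-corrected
  agreement with Landis–Koch interpretation bands, nomological
  containment of published red-flag factor lists, ROC/AUC predictive
  validation with deterministic sensitivity variations, and the
  seven-domain validation-framework registry (four implementable without
  a comparator model).
- **Synthetic data** (`spinebn.simulate`): seeded forward-sampled labeled
  cases, rating matrices at controlled concordance, agreement tables at
  controlled agreement — everything the harness needs with no external
  data.

The elicited probability tables and codified patient cases behind the
original model were never published; the packaged structure is a tagged
reconstruction and all probabilities here are documented synthetic
parameterizations (see `docs/methods.md`).

## Worked example

```python
import spinebn as s

model = s.build_default_model(seed=7)   # packaged structure + seeded parameters

baseline = s.posterior_judgments(model, s.Evidence({}))
print("baseline CES:", f"{baseline.posteriors['cauda_equina_syndrome']:.4f}")

worried = s.Evidence({
    "saddle_sensory_disturbance": "present",
    "bladder_function_change": "present",
    "bilateral_radicular_pain": "present",
})
report = s.posterior_judgments(model, worried)
for name in ("cauda_equina_syndrome", "fracture", "nerve_root_condition"):
    print(f"{name}: {report.posteriors[name]:.4f}")
```

prints

```
baseline CES: 0.0312
cauda_equina_syndrome: 0.9815
fracture: 0.0363
nerve_root_condition: 0.0278
```

With no findings entered, cauda equina syndrome sits at its rare
baseline (3.1%). Observing the classic triad — saddle sensory
disturbance, bladder change, bilateral radicular pain — drives its
posterior to 98%, while fracture (which shares two of those signs) rises
only slightly and nerve root condition stays near baseline: the three
signs together are far better explained by CES, and explaining-away
keeps the competing conditions down. Every node left out of the evidence
is treated as unknown and marginalized.

The same pipeline is available from a shell:

```sh
spinebn validate-network          # layer counts, acyclicity, provenance
spinebn demo --seed 7             # full validation harness on the packaged model
spinebn simulate --n 500 --seed 42 --out cases.csv
spinebn roc --cases cases.csv --seed 42
spinebn consensus --ratings ratings.csv --median-min 2 --ipr-max 1
spinebn agreement --table reviews.csv
spinebn containment
```

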