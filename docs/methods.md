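# Methods

## The model

`spinebn` encodes an expert-elicited causal Bayesian network for screening
low back pain presentations for serious spinal pathology (SSP). The
structure is a three-layer directed acyclic graph over 38 binary
(present/absent) variables:

- **Risk factors** (10): antecedent history items such as trauma, steroid
  use, poor bone health, immunosuppression, or a history of cancer.
- **Judgment factors** (11): the candidate explanations a clinician weighs —
  cauda equina syndrome (CES), space-occupying lesion/cancer, fracture,
  infective condition, inflammatory condition, cord compression, nerve root
  condition, and four non-pathology impact variables (irritability of pain,
  depression, stress, anxiety). The term *judgment factor* is deliberate:
  the tool produces a risk judgment, not a diagnosis.
- **Signs and symptoms** (17): observable findings such as saddle sensory
  disturbance, bilateral radicular pain, fever, weight loss, or night pain.

Edges run only risk→judgment and judgment→sign, mirroring the causal
reading "risk factors raise the probability of a pathology; a pathology
raises the probability of its signs". The layer ordering makes the graph
acyclic by construction; `validate_structure` checks acyclicity
independently by graph search anyway.

Every node and edge carries a **provenance tag** (`table3`,
`results_text`, `figure6_caption`, `placeholder`). The elicited edge list
was never published in full; only edges traceable to the published factor
tables and result narratives are tagged with a source, and the two
cord-compression→motor-sign edges are declared `placeholder`
reconstructions (cord compression was reported as "not defined well
enough" by the elicitation panel). The packaged JSON file is the declared
source of truth for node identities; `provenance_report` makes the
reconstructed/declared split auditable. One modelling choice deserves
note: the published factor lists attest eleven distinct risk-layer items
while the layer is fixed at ten variables, so uveitis and inflammatory
bowel disease — jointly predictive of inflammatory spinal disease and
frequently comorbid — are carried as a single comorbidity node
(`uveitis_or_ibd`) with both reference aliases mapping to it.

## Parameterization

Non-root nodes use a **leaky noisy-OR** conditional model:

    P(child = present | active parents A) = 1 − (1 − λ) · ∏_{i∈A} (1 − s_i)

with leak λ ∈ [0, 1) and one link strength s_i per edge. This is the
standard completion model for expert-elicited cause→effect networks: it
needs exactly one number per edge plus a background rate, which matches
scenario-based probability elicitation, and it is monotone — adding an
active cause never lowers the probability of the effect.
`noisy_or_table` expands a spec to an explicit CPT; expansion is validated
row-by-row (rows sum to 1 within 1e−9) and agrees with the closed form to
1e−12.

The elicited probabilities behind the published model are not public, so
the package draws **documented synthetic parameter sets**
(`random_parameterization`, seeded, PCG64):

| quantity | default range | rationale |
| --- | --- | --- |
| risk-factor prior | U(0.05, 0.4) | history items are common but not universal |
| judgment leak | U(0.001, 0.02) | pathologies arise rarely without a modelled risk factor |
| sign leak | U(0.01, 0.1) | background symptom rates in back-pain populations |
| link strength | U(0.2, 0.9) | plausible span from weak to strong causal links |
| root judgment prior | U(0.01, 0.08) | rare conditions |

`default_parameterization` additionally **calibrates each judgment
factor's baseline**: a target no-evidence marginal is drawn from
U(0.01, 0.08), the leak is set to half the target, and the incoming link
strengths are rescaled by a common factor (Brent root finding on the
noisy-OR marginal, exact because risk parents are independent roots) so
the marginal hits the target. Serious spinal pathologies are rare;
without this calibration a judgment node with several risk parents would
start near 0.4 before any evidence, which no clinician would accept as a
baseline. Elicited 0–3 edge strengths, where present on an edge, map to
link strengths {0→0.0, 1→0.3, 2→0.6, 3→0.85}, preserving elicited order;
the map is overridable in the parameter file.

## Inference

Posteriors are exact, computed by **variable elimination** with a min-fill
ordering and deterministic lexicographic tie-breaks (reproducible
diagnostics). Evidence is a partial map node→state; *unknown is absence
from the map*, never a state — the unobserved node is marginalized, which
is precisely the "fall back to the prior baseline" behavior a screening
tool needs for unanswered questions. Computation stays in linear space
with a single normalization at the end: at ≤38 binary nodes underflow is
not a risk, and linear space keeps results directly comparable with the
full-joint **enumeration oracle** (`brute_force_posterior`, guarded to 20
nodes), against which elimination is tested to 1e−9 on hundreds of random
layered networks.

`posterior_judgments` refuses evidence on judgment nodes (prediction
mode); the lower-level `query_posterior` accepts any evidence, including
conditioning on a queried node (returns a point mass).

## Consensus mathematics

Panel scores live on the 0–3 relationship scale. Consensus per item is
the **median** plus the **30th–70th interpercentile range (IPR)**; an
item becomes an edge when median ≥ 2 and IPR ≤ 1 (both thresholds
configurable and recorded in every result). Percentiles default to the
**inverted-CDF (closest-rank)** convention: on small integer panels it
returns observed scores, so the IPR is an integer on the same scale as
the ratings; any numpy percentile method can be configured instead.
Rank aggregation orders items by ascending median rank with
lexicographic tie-breaks. The symmetry-adjusted IPRAS disagreement rule
is available (`consensus.ipras`) but off by default, with its classic
constants rescaled from the 1–9 appropriateness scale to 0–3.

## Validation instruments

- **Gwet AC2** (`gwet_ac2`): chance-corrected weighted agreement,
  computed exactly as the count-based formulation (observed weighted
  agreement over items with ≥2 raters; chance term from mean category
  prevalences scaled by T_w/(q(q−1))). Identity weights reduce AC2 to
  AC1, which the tests verify against an independent first-principles
  computation. AC2 is preferred over kappa here because reviewer
  judgments are prevalence-skewed (most variables were endorsed), where
  kappa collapses.
- **Landis–Koch bands** (`landis_koch`): half-open intervals
  (−∞,0) Poor, [0,0.2] Slight, (0.2,0.4] Fair, (0.4,0.6] Moderate,
  (0.6,0.8] Substantial, (0.8,1] Almost perfect. Published band tables
  leave gaps at boundaries (0.2 vs 0.21); half-open intervals make the
  function total and monotone while agreeing with all printed examples.
- **Nomological containment** (`containment_check`): for each condition,
  the packaged reference lists the published guideline/consensus factors
  with an alias to a network node (or none); a factor is *contained* when
  its node exists **and is directly linked** to the condition. On the
  packaged structure this reproduces the published pattern, including the
  weak spots: 1/7 nerve-root guideline factors and 2/10 fracture factors
  contained.
- **ROC/AUC** (`roc_auc`): area by rank-sum pair counting, positive–
  negative ties counting ½; equals trapezoidal integration of the
  tie-corrected ROC curve (verified to 1e−12). Scores are rounded to 12
  decimals before ranking: posterior scores are meaningless below the CPT
  normalization tolerance, and machine-epsilon rank noise would otherwise
  turn exact ties (e.g., a d-separated condition under a null
  parameterization) into spurious orderings. Single-class label sets
  yield an explicitly undefined AUC with a diagnostic, not an exception.
- **Sensitivity variations** (`apply_variation`): `higher_risk` sets the
  first not-yet-present sign linked to the case's condition (canonical
  node order — deterministic, not random, for reproducibility);
  `add_cancer_symptoms` / `add_inflammatory_symptoms` set all signs
  linked to the respective condition. On the packaged structure the
  inflammatory condition has no linked signs (its published factors are
  all risk-type), so that variation is a no-op there — faithful to the
  elicited structure rather than a defect.

## Synthetic data: what it emulates, and what it does not

`forward_sample` draws labeled cases by ancestral sampling: evidence is
the full risk + sign layer; the sampled judgment states become the 0/1
labels. `synth_rating_matrix` and `synth_agreement_table` mix designated
answers with uniform noise at a controlled concordance/agreement level.
`auc_recovery_experiment` chains sampling and predictive validation; under
a strong parameterization (links ≥ 0.8, leaks ≤ 0.01) the CES AUC exceeds
0.9 at n = 2000, and under a null (condition's links zeroed) it sits at
chance, which brackets the instrument's behavior from both sides.

These generators emulate the *statistical shape* of the study inputs, not
clinical reality: cases are fully observed (real presentations have many
unknowns), labels come from the model itself (no label noise, no
diagnostic ambiguity), prevalences follow the configured priors rather
than epidemiology, and rating noise is exchangeable across raters (real
panels have rater effects). Passing tests therefore demonstrate that the
instruments are mathematically correct and that the pipeline recovers
known signal — not that the packaged network predicts real patients; the
published headline AUCs depended on elicited tables and codified cases
that were never made public and are not reproduced here.

## Numerical choices

- CPT row normalization tolerance 1e−9; noisy-OR expansion vs closed form
  1e−12; elimination vs enumeration 1e−9.
- ROC scores rounded to 12 decimals (tie handling, above).
- Percentile method inverted-CDF by default, configurable.
- RNG: numpy `default_rng` (PCG64) everywhere; every public generator
  takes an explicit integer seed.
- Degenerate inputs: zero-probability evidence raises; empty score lists
  raise; single-class AUC and all-single-rater agreement are reported
  undefined (the former as a value, the latter as an error, matching how
  each is consumed).

## Problem sizes

The test suite and the acceptance script run the elimination-vs-
enumeration check on 200 random ≤12-node networks, the AUC identity on
100 random score/label sets, signal recovery at n = 2000 cases, and
sampling consistency at n = 10 000 cases; together these complete in
about a minute on one core, which we consider ample evidence given the
exact (non-stochastic) nature of most of the checks.

## Known limitations

- The packaged structure is a *reconstruction*: only published fragments
  of the elicited network are recoverable, and the provenance tags are
  the honest boundary of that knowledge.
- Judgment factors are mutually independent a priori (no judgment→
  judgment edges); comorbidity correlations enter only through shared
  risk parents and explaining-away at shared signs.
- All variables are binary; ordinal severity (e.g., age bands, pain
  levels) is collapsed to present/absent.
- No parameter learning from clinical data; the synthetic
  parameterizations are stand-ins for elicited values, not estimates.
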