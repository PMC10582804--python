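"""Validation instruments for the elicited screening network.

Four of the seven domains of the expert-model validation framework are
implemented computationally: *content/face* validation via the Gwet AC2
chance-corrected agreement coefficient with Landis-Koch interpretation
bands, *nomological* validation via containment checks of the structure
against published red-flag factor lists, and *predictive* validation via
ROC/AUC over labeled patient cases, including deterministic sensitivity
variations of the case evidence. The remaining domains (concurrent,
convergent, discriminant) need a comparator model and are registered as
deferred.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

from .inference import Evidence, posterior_judgments
from .network import NetworkDefinition
from .parameters import ParameterizedNetwork

#: The six judgment factors with predictable outcome labels.
PREDICTABLE_CONDITIONS = (
    "cauda_equina_syndrome",
    "space_occupying_lesion",
    "fracture",
    "infective_condition",
    "inflammatory_condition",
    "nerve_root_condition",
)

VARIATION_KINDS = ("higher_risk", "add_cancer_symptoms", "add_inflammatory_symptoms")

#: Landis-Koch interpretation bands as half-open intervals (total and monotone).
LANDIS_KOCH_BANDS = (
    (float("-inf"), 0.0, "Poor"),  # coefficient < 0
    (0.0, 0.2, "Slight"),  # 0 <= c <= 0.2
    (0.2, 0.4, "Fair"),
    (0.4, 0.6, "Moderate"),
    (0.6, 0.8, "Substantial"),
    (0.8, 1.0, "Almost perfect"),
)
BAND_ORDER = ("Poor", "Slight", "Fair", "Moderate", "Substantial", "Almost perfect")


class AgreementError(ValueError):
    """Agreement statistic undefined or inputs inconsistent."""


class LabelError(ValueError):
    """A case carries a label outside the six predictable conditions."""


# ---------------------------------------------------------------------------
# inter-rater agreement (Gwet AC2)


@dataclass
class AgreementTable:
    """Items x raters categorical ratings; NaN/None marks a missing rating."""

    ratings: pd.DataFrame
    categories: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.categories:
            observed = sorted(
                {str(v) for v in self.ratings.to_numpy().ravel() if not pd.isna(v)}
            )
            self.categories = tuple(observed)
        if len(self.categories) < 2:
            raise AgreementError("need at least 2 categories")


@dataclass(frozen=True)
class WeightScheme:
    """Symmetric q x q agreement weights with a unit diagonal.

    Identity weights (all off-diagonal zero) reduce AC2 to the unweighted
    AC1 coefficient.
    """

    categories: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        q = len(self.categories)
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (q, q):
            raise AgreementError(f"weight matrix must be {q}x{q}")
        if not np.allclose(np.diag(m), 1.0):
            raise AgreementError("weight diagonal must be all ones")
        if not np.allclose(m, m.T):
            raise AgreementError("weights must be symmetric")
        if (m < 0).any() or (m > 1).any():
            raise AgreementError("weights must lie in [0, 1]")
        object.__setattr__(self, "matrix", m)


def identity_weights(categories) -> WeightScheme:
    q = len(tuple(categories))
    return WeightScheme(tuple(categories), np.eye(q))


def linear_weights(categories) -> WeightScheme:
    """Ordinal weights 1 - |k-l|/(q-1) over the given category order."""
    cats = tuple(categories)
    q = len(cats)
    idx = np.arange(q)
    m = 1.0 - np.abs(idx[:, None] - idx[None, :]) / (q - 1)
    return WeightScheme(cats, m)


@dataclass
class AgreementResult:
    p_a: float
    p_e: float
    coefficient: float
    band: str
    n_items_scored: int


def gwet_ac2(
    table: AgreementTable, weights: WeightScheme | None = None
) -> AgreementResult:
    """Gwet's AC2 chance-corrected weighted inter-rater agreement.

    With r_ik raters placing item i in category k, r_i raters for item i and
    weighted counts r*_ik = sum_l w_kl r_il:

        p_a = mean over items with r_i >= 2 of
              sum_k r_ik (r*_ik - 1) / (r_i (r_i - 1))
        pi_k = mean over all items of r_ik / r_i
        p_e = T_w / (q (q - 1)) * sum_k pi_k (1 - pi_k),  T_w = sum_kl w_kl
        AC2 = (p_a - p_e) / (1 - p_e)

    Identity weights give AC1. Items rated by a single rater contribute to
    the chance term only; if no item has two raters the observed agreement
    is undefined and an AgreementError is raised.
    """
    if weights is None:
        weights = identity_weights(table.categories)
    if tuple(weights.categories) != tuple(table.categories):
        raise AgreementError(
            f"weight categories {weights.categories} != table categories "
            f"{table.categories}"
        )
    cats = list(table.categories)
    q = len(cats)
    w = weights.matrix

    counts = []  # r_ik per item
    for _, row in table.ratings.iterrows():
        vals = [str(v) for v in row if not pd.isna(v)]
        unknown = set(vals) - set(cats)
        if unknown:
            raise AgreementError(f"ratings outside declared categories: {sorted(unknown)}")
        counts.append(np.array([vals.count(c) for c in cats], dtype=float))
    counts = np.array(counts)
    if counts.size == 0 or counts.sum() == 0:
        raise AgreementError("agreement table has no ratings")
    r_i = counts.sum(axis=1)

    multi = r_i >= 2
    if not multi.any():
        raise AgreementError("every item has a single rater; agreement undefined")
    r_star = counts @ w.T  # r*_ik = sum_l w_kl r_il
    num = (counts[multi] * (r_star[multi] - 1.0)).sum(axis=1)
    p_a = float(np.mean(num / (r_i[multi] * (r_i[multi] - 1.0))))

    rated = r_i > 0
    pi_k = (counts[rated] / r_i[rated, None]).mean(axis=0)
    t_w = float(w.sum())
    p_e = float(t_w / (q * (q - 1)) * (pi_k * (1.0 - pi_k)).sum())
    if p_e >= 1.0:
        raise AgreementError("chance agreement is 1; coefficient undefined")
    coefficient = (p_a - p_e) / (1.0 - p_e)
    return AgreementResult(
        p_a=p_a,
        p_e=p_e,
        coefficient=float(coefficient),
        band=landis_koch(coefficient),
        n_items_scored=int(multi.sum()),
    )


def landis_koch(coefficient: float) -> str:
    """Interpretation band for an agreement coefficient (total on (-inf, 1])."""
    if coefficient > 1.0:
        raise AgreementError(f"agreement coefficient cannot exceed 1: {coefficient}")
    if coefficient < 0.0:
        return "Poor"
    for low, high, label in LANDIS_KOCH_BANDS[1:]:
        if low < coefficient <= high or (coefficient == 0.0 and label == "Slight"):
            return label
    return "Slight"  # coefficient == 0 handled above; unreachable fallback


def band_summary(coefficients: dict[str, float]) -> dict:
    """Band label per variable plus counts per band (zero-filled)."""
    labels = {name: landis_koch(v) for name, v in coefficients.items()}
    counts = {band: 0 for band in BAND_ORDER}
    for band in labels.values():
        counts[band] += 1
    return {"labels": labels, "counts": counts}


# ---------------------------------------------------------------------------
# nomological containment


@dataclass
class ContainmentRow:
    condition: str
    factor: str
    node: str | None
    contained: bool


@dataclass
class ContainmentReport:
    rows: list[ContainmentRow]

    def per_condition(self) -> dict[str, tuple[int, int]]:
        """condition -> (contained count, total factors)."""
        out: dict[str, tuple[int, int]] = {}
        for row in self.rows:
            c, t = out.get(row.condition, (0, 0))
            out[row.condition] = (c + int(row.contained), t + 1)
        return out


def containment_check(
    net: NetworkDefinition, reference: dict[str, list[dict]]
) -> ContainmentReport:
    """Check which published factors for each condition are linked in the net.

    ``reference`` maps a condition node name to a list of factor entries
    ``{"factor": display name, "node": network node alias or None}``. A
    factor counts as contained when its alias node exists in the network and
    is directly linked (either direction) to the condition node.
    """
    judgments = set(net.judgment_names())
    rows = []
    for condition, factors in reference.items():
        if condition not in judgments:
            raise LabelError(f"unknown condition {condition!r} in reference")
        linked = set(net.parents(condition)) | set(net.children(condition))
        for entry in factors:
            node = entry.get("node")
            contained = bool(node) and net.has_node(node) and node in linked
            rows.append(
                ContainmentRow(
                    condition=condition,
                    factor=entry["factor"],
                    node=node,
                    contained=contained,
                )
            )
    return ContainmentReport(rows=rows)


# ---------------------------------------------------------------------------
# predictive validation


@dataclass
class CaseRecord:
    """One patient presentation: evidence plus 0/1 outcome labels."""

    id: str
    evidence: Evidence
    labels: dict[str, int] = field(default_factory=dict)
    source: str = "synthetic"

    def __post_init__(self) -> None:
        bad = sorted(set(self.labels) - set(PREDICTABLE_CONDITIONS))
        if bad:
            raise LabelError(
                f"case {self.id!r}: labels restricted to the six predictable "
                f"conditions; got {bad}"
            )
        for k, v in self.labels.items():
            if v not in (0, 1):
                raise LabelError(f"case {self.id!r}: label {k}={v!r} must be 0 or 1")


@dataclass
class RocResult:
    condition: str
    auc: float | None
    fpr: np.ndarray
    tpr: np.ndarray
    n_pos: int
    n_neg: int
    diagnostic: str = ""


def roc_auc(scores, labels, condition: str = "") -> RocResult:
    """AUC by rank-sum pair counting; positive-negative score ties count 0.5.

    Equals the probability that a random positive outscores a random
    negative. With a single label class the AUC is undefined and reported
    as None with a diagnostic rather than raised.

    Scores are rounded to 12 decimals before ranking: posterior scores are
    only meaningful to about the CPT normalization tolerance, and ranking
    at machine-epsilon granularity would turn genuinely tied scores into
    spurious orderings.
    """
    s = np.round(np.asarray(list(scores), dtype=float), 12)
    y = np.asarray(list(labels), dtype=int)
    if s.shape != y.shape:
        raise ValueError(f"scores ({s.size}) and labels ({y.size}) differ in length")
    if not np.isin(y, (0, 1)).all():
        raise LabelError("labels must be 0/1")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        return RocResult(
            condition=condition,
            auc=None,
            fpr=np.array([]),
            tpr=np.array([]),
            n_pos=n_pos,
            n_neg=n_neg,
            diagnostic=f"single-class labels (pos={n_pos}, neg={n_neg}); AUC undefined",
        )
    ranks = rankdata(s)  # average ranks handle ties as 0.5 wins
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, _ = _sk_roc_curve(y, s, drop_intermediate=False)
    return RocResult(
        condition=condition,
        auc=float(auc),
        fpr=fpr,
        tpr=tpr,
        n_pos=n_pos,
        n_neg=n_neg,
    )


def apply_variation(
    case: CaseRecord,
    variation: str,
    net: NetworkDefinition,
    condition: str | None = None,
) -> CaseRecord:
    """Deterministic sensitivity variation of a case's evidence.

    higher_risk: set to present the first sign (canonical network node
    order) linked to the case's labeled condition not already present.
    add_cancer_symptoms / add_inflammatory_symptoms: set to present every
    sign linked to the space-occupying lesion / inflammatory condition node.
    Labels are never changed.
    """
    if variation not in VARIATION_KINDS:
        raise ValueError(f"unknown variation {variation!r}; pick from {VARIATION_KINDS}")
    obs = dict(case.evidence.observations)
    if variation == "higher_risk":
        if condition is None:
            positives = [c for c in PREDICTABLE_CONDITIONS if case.labels.get(c) == 1]
            if not positives:
                raise ValueError(
                    f"case {case.id!r}: higher_risk needs a labeled (or explicit) "
                    "target condition"
                )
            condition = positives[0]
        linked_signs = [
            n.name
            for n in net.nodes
            if n.layer == "sign_symptom" and n.name in net.children(condition)
        ]
        unset = [s for s in linked_signs if obs.get(s) != "present"]
        if not unset:
            raise ValueError(
                f"case {case.id!r}: every sign linked to {condition!r} is already "
                "present; higher_risk variation exhausted"
            )
        obs[unset[0]] = "present"
    else:
        target = (
            "space_occupying_lesion"
            if variation == "add_cancer_symptoms"
            else "inflammatory_condition"
        )
        for n in net.nodes:
            if n.layer == "sign_symptom" and n.name in net.children(target):
                obs[n.name] = "present"
    return CaseRecord(
        id=f"{case.id}+{variation}",
        evidence=Evidence(obs),
        labels=dict(case.labels),
        source=f"{case.source}/variation",
    )


def predictive_validation(
    pnet: ParameterizedNetwork, cases: list[CaseRecord]
) -> dict[str, RocResult]:
    """ROC/AUC per predictable condition over posterior scores for the cases."""
    if not cases:
        raise ValueError("predictive validation needs at least one case")
    score_rows = []
    for case in cases:
        try:
            report = posterior_judgments(pnet, case.evidence)
        except Exception as err:
            raise type(err)(f"case {case.id!r}: {err}") from err
        score_rows.append(report.posteriors)
    results = {}
    for condition in PREDICTABLE_CONDITIONS:
        labeled = [
            (row[condition], case.labels[condition])
            for row, case in zip(score_rows, cases)
            if condition in case.labels
        ]
        if not labeled:
            results[condition] = RocResult(
                condition=condition,
                auc=None,
                fpr=np.array([]),
                tpr=np.array([]),
                n_pos=0,
                n_neg=0,
                diagnostic="no labels supplied for this condition",
            )
            continue
        scores, labels = zip(*labeled)
        results[condition] = roc_auc(scores, labels, condition=condition)
    return results


# ---------------------------------------------------------------------------
# validation-framework registry


def validation_framework() -> list[dict]:
    """The seven-domain expert-model validation registry with per-domain status."""
    from .io import load_packaged_framework

    return load_packaged_framework()


def framework_summary() -> dict:
    domains = validation_framework()
    implemented = [d["domain"] for d in domains if d["implemented"]]
    deferred = [d["domain"] for d in domains if not d["implemented"]]
    return {
        "total": len(domains),
        "implemented": len(implemented),
        "implemented_domains": implemented,
        "deferred_domains": deferred,
    }


__all__ = [
    "PREDICTABLE_CONDITIONS",
    "VARIATION_KINDS",
    "LANDIS_KOCH_BANDS",
    "BAND_ORDER",
    "AgreementError",
    "LabelError",
    "AgreementTable",
    "WeightScheme",
    "AgreementResult",
    "identity_weights",
    "linear_weights",
    "gwet_ac2",
    "landis_koch",
    "band_summary",
    "ContainmentRow",
    "ContainmentReport",
    "containment_check",
    "CaseRecord",
    "RocResult",
    "roc_auc",
    "apply_variation",
    "predictive_validation",
    "validation_framework",
    "framework_summary",
]
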