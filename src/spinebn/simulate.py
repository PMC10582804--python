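"""Seeded synthetic generators: labeled cases, rating matrices, agreement tables.

The published model's elicited probability tables and codified patient cases
are not public, so every downstream instrument is exercised on controlled
synthetic inputs instead: ancestral forward samples from a parameterized
network stand in for labeled clinical cases, and concordance/agreement
parameters let the consensus and agreement statistics be tested at known
signal levels.

All generators are pure functions of their arguments and a seed, using
numpy's default_rng (PCG64), so fixtures are byte-reproducible across runs
and platforms.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .consensus import RatingMatrix, VALID_SCORES
from .inference import Evidence
from .network import NetworkDefinition
from .parameters import (
    ParameterizedNetwork,
    ParameterSet,
    attach_parameters,
    random_parameterization,
)
from .validation import (
    AgreementTable,
    CaseRecord,
    PREDICTABLE_CONDITIONS,
    predictive_validation,
)


def _topological_order(pnet: ParameterizedNetwork) -> list[str]:
    order: list[str] = []
    placed: set[str] = set()
    pending = list(pnet.node_names())
    while pending:
        progressed = False
        for name in list(pending):
            if all(p in placed for p in pnet.net.parents(name)):
                order.append(name)
                placed.add(name)
                pending.remove(name)
                progressed = True
        if not progressed:  # cannot happen on a validated DAG
            raise ValueError("network contains a cycle")
    return order


def forward_sample(
    pnet: ParameterizedNetwork, n: int, seed: int
) -> list[CaseRecord]:
    """Ancestral sampling: n labeled cases, judgment states hidden into labels.

    Evidence carries only the risk and sign layers (everything a clinician
    could observe); the sampled judgment states become the 0/1 outcome
    labels for the six predictable conditions.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    order = _topological_order(pnet)
    layer = {node.name: node.layer for node in pnet.net.nodes}
    # precompute cumulative rows once; sampling is then one uniform per node
    cumrows = {
        name: {
            combo: np.cumsum(dist) for combo, dist in pnet.cpts[name].rows.items()
        }
        for name in order
    }
    cases = []
    width = max(4, len(str(n)))
    for i in range(n):
        world: dict[str, str] = {}
        for name in order:
            t = pnet.cpts[name]
            combo = tuple(world[p] for p in t.parents)
            k = int(np.searchsorted(cumrows[name][combo], rng.random(), side="right"))
            world[name] = t.child_states[min(k, len(t.child_states) - 1)]
        observations = {
            name: state
            for name, state in world.items()
            if layer[name] != "judgment_factor"
        }
        labels = {
            c: int(world[c] == "present")
            for c in PREDICTABLE_CONDITIONS
            if pnet.net.has_node(c)
        }
        cases.append(
            CaseRecord(
                id=f"case_{i:0{width}d}",
                evidence=Evidence(observations),
                labels=labels,
                source="synthetic/forward_sample",
            )
        )
    return cases


def synth_rating_matrix(
    n_raters: int,
    n_items: int,
    concordance: float,
    seed: int,
    designated_scores=None,
) -> RatingMatrix:
    """Panel ratings mixing a designated score with uniform 0-3 noise.

    Each individual rating equals the item's designated score with
    probability ``concordance`` and is otherwise uniform over 0-3;
    concordance 1 gives perfectly constant columns, concordance 0 pure
    noise. Designated scores default to seeded uniform draws.
    """
    if not 0.0 <= concordance <= 1.0:
        raise ValueError("concordance must be in [0, 1]")
    if n_raters < 1 or n_items < 1:
        raise ValueError("need at least one rater and one item")
    rng = np.random.default_rng(seed)
    if designated_scores is None:
        designated = rng.integers(0, 4, size=n_items)
    else:
        designated = np.asarray(list(designated_scores), dtype=int)
        if designated.size != n_items:
            raise ValueError("designated_scores length must equal n_items")
        if not np.isin(designated, VALID_SCORES).all():
            raise ValueError("designated scores must be on the 0-3 scale")
    use_designated = rng.random(size=(n_items, n_raters)) < concordance
    noise = rng.integers(0, 4, size=(n_items, n_raters))
    scores = np.where(use_designated, designated[:, None], noise)
    frame = pd.DataFrame(
        scores,
        index=[f"item_{i:03d}" for i in range(n_items)],
        columns=[f"rater_{j:02d}" for j in range(n_raters)],
        dtype=float,
    )
    return RatingMatrix(scores=frame)


def synth_agreement_table(
    n_raters: int,
    n_items: int,
    target_agreement: float,
    seed: int,
    categories: tuple[str, ...] = ("agree", "disagree"),
    designated=None,
) -> AgreementTable:
    """Binary (by default) categorical ratings at a controlled agreement level.

    Each rating matches the item's designated category with probability
    ``target_agreement`` and otherwise flips to a uniformly chosen other
    category.
    """
    if not 0.0 <= target_agreement <= 1.0:
        raise ValueError("target_agreement must be in [0, 1]")
    if len(categories) < 2:
        raise ValueError("need at least 2 categories")
    rng = np.random.default_rng(seed)
    q = len(categories)
    if designated is None:
        designated_idx = rng.integers(0, q, size=n_items)
    else:
        designated_idx = np.asarray(
            [categories.index(c) for c in designated], dtype=int
        )
        if designated_idx.size != n_items:
            raise ValueError("designated length must equal n_items")
    match = rng.random(size=(n_items, n_raters)) < target_agreement
    offsets = rng.integers(1, q, size=(n_items, n_raters))
    idx = np.where(
        match, designated_idx[:, None], (designated_idx[:, None] + offsets) % q
    )
    frame = pd.DataFrame(
        np.asarray(categories, dtype=object)[idx],
        index=[f"item_{i:03d}" for i in range(n_items)],
        columns=[f"rater_{j:02d}" for j in range(n_raters)],
    )
    return AgreementTable(ratings=frame, categories=tuple(categories))


def strong_parameterization(net: NetworkDefinition, seed: int) -> ParameterSet:
    """High-signal parameter set: strong links (>= 0.8), tiny leaks (<= 0.01).

    Judgment baselines sit near 0.05-0.1 so a moderate sample contains both
    classes; sign nodes fire almost only when a parent condition is
    present, making positives cleanly separable.
    """
    return random_parameterization(
        net,
        seed,
        judgment_prior=(0.05, 0.1),
        judgment_leak=(0.001, 0.01),
        sign_leak=(0.001, 0.01),
        link=(0.8, 0.95),
        judgment_marginal_target=None,
    )


def null_parameterization(
    net: NetworkDefinition, seed: int, condition: str
) -> ParameterSet:
    """Strong parameter set with every link of ``condition``'s sign children zeroed.

    Under this null the condition's signs carry no information about it, so
    its AUC should sit at chance level.
    """
    params = strong_parameterization(net, seed)
    for child in net.children(condition):
        spec = params.tables[child]
        strengths = dict(spec.link_strength)
        strengths[condition] = 0.0
        params.tables[child] = type(spec)(
            child=child, leak=spec.leak, link_strength=strengths
        )
    # also cut any direct risk->condition links so evidence is uninformative
    for parent in net.parents(condition):
        spec = params.tables.get(condition)
        if spec is not None:
            strengths = dict(spec.link_strength)
            strengths[parent] = 0.0
            params.tables[condition] = type(spec)(
                child=condition, leak=spec.leak, link_strength=strengths
            )
    return params


def auc_recovery_experiment(
    pnet: ParameterizedNetwork, n: int, seed: int
) -> dict[str, dict]:
    """Forward-sample n cases, run predictive validation, report AUC per condition.

    Returns ``{condition: {"auc": float | None, "n_pos": int, "n_neg": int,
    "diagnostic": str}}``; a single-class sample leaves the AUC undefined
    with a diagnostic suggesting a larger n or prior.
    """
    cases = forward_sample(pnet, n, seed)
    rocs = predictive_validation(pnet, cases)
    out = {}
    for condition, roc in rocs.items():
        diagnostic = roc.diagnostic
        if roc.auc is None and not diagnostic:
            diagnostic = "single-class sample; raise n or the condition's prior"
        out[condition] = {
            "auc": roc.auc,
            "n_pos": roc.n_pos,
            "n_neg": roc.n_neg,
            "diagnostic": diagnostic,
        }
    return out


def random_layered_network(seed: int, max_nodes: int = 12) -> NetworkDefinition:
    """Random small 3-layer structure (1-3 risk, 1-3 judgment, rest signs).

    Used for stress-testing inference against the enumeration oracle; edge
    presence is Bernoulli(0.6) within the allowed layer ordering.
    """
    from .network import DirectedEdge, VariableNode

    rng = np.random.default_rng(seed)
    n_r = int(rng.integers(1, 4))
    n_j = int(rng.integers(1, 4))
    n_s = int(rng.integers(1, max_nodes - n_r - n_j + 1))
    nodes = (
        [VariableNode(f"r{i}", "risk_factor", provenance="table3") for i in range(n_r)]
        + [VariableNode(f"j{i}", "judgment_factor", provenance="table3") for i in range(n_j)]
        + [VariableNode(f"s{i}", "sign_symptom", provenance="table3") for i in range(n_s)]
    )
    edges = []
    for j in range(n_j):
        for r in range(n_r):
            if rng.random() < 0.6:
                edges.append(DirectedEdge(f"r{r}", f"j{j}", provenance="table3"))
    for s_i in range(n_s):
        for j in range(n_j):
            if rng.random() < 0.6:
                edges.append(DirectedEdge(f"j{j}", f"s{s_i}", provenance="table3"))
    return NetworkDefinition(nodes=nodes, edges=edges)


def random_layered_model(seed: int, max_nodes: int = 12) -> ParameterizedNetwork:
    """Random small structure with a random parameterization under one seed."""
    net = random_layered_network(seed, max_nodes=max_nodes)
    return attach_parameters(net, random_parameterization(net, seed))


def random_evidence(
    pnet: ParameterizedNetwork,
    seed: int,
    layers: tuple[str, ...] = ("risk_factor", "sign_symptom"),
) -> Evidence:
    """Random partial evidence: each eligible node observed w.p. 0.5."""
    rng = np.random.default_rng(seed)
    obs = {}
    for node in pnet.net.nodes:
        if node.layer in layers and rng.random() < 0.5:
            obs[node.name] = "present" if rng.random() < 0.5 else "absent"
    return Evidence(obs)


def cases_to_frame(cases: list[CaseRecord], net: NetworkDefinition) -> pd.DataFrame:
    """Wide CSV-ready frame: id, source, one evidence column per non-judgment node
    (present/absent/unknown), and one label_<condition> column per labeled condition."""
    non_judgment = [n.name for n in net.nodes if n.layer != "judgment_factor"]
    rows = []
    for case in cases:
        row: dict[str, object] = {"id": case.id, "source": case.source}
        for name in non_judgment:
            row[name] = case.evidence.observations.get(name, "unknown")
        for c in PREDICTABLE_CONDITIONS:
            if c in case.labels:
                row[f"label_{c}"] = case.labels[c]
        rows.append(row)
    return pd.DataFrame(rows)


__all__ = [
    "forward_sample",
    "random_layered_network",
    "random_layered_model",
    "random_evidence",
    "synth_rating_matrix",
    "synth_agreement_table",
    "strong_parameterization",
    "null_parameterization",
    "auc_recovery_experiment",
    "cases_to_frame",
]
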