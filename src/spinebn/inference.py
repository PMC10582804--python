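"""Exact posterior computation over the screening network.

Queries are answered by variable elimination with a min-fill ordering; a
full-joint enumeration oracle (guarded to small networks) backs the
equivalence tests. Unknown findings are handled by omission from the
evidence map: an unobserved node is marginalized, which is exactly the
"prior baseline assumption" behavior a screening tool needs when the
clinician cannot answer a question.

Probabilities are kept in linear space with renormalization after
conditioning; the networks involved are small (<= 38 binary nodes), so
underflow is not a concern and results stay directly comparable with the
enumeration oracle.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .parameters import ParameterizedNetwork

BRUTE_FORCE_MAX_NODES = 20


class EvidenceError(ValueError):
    """Evidence refers to an unknown node or an illegal state."""


@dataclass(frozen=True)
class Evidence:
    """Per-node observations; nodes absent from the map are unknown.

    "unknown" is never a value here — leaving a node out *is* the unknown
    condition, and inference marginalizes over it.
    """

    observations: dict[str, str] = field(default_factory=dict)

    def validate(self, pnet: ParameterizedNetwork) -> None:
        for name, state in self.observations.items():
            if not pnet.net.has_node(name):
                raise EvidenceError(f"evidence names unknown node {name!r}")
            if state not in pnet.states(name):
                raise EvidenceError(
                    f"evidence state {state!r} is not a state of node {name!r} "
                    f"(legal: {pnet.states(name)})"
                )

    def __contains__(self, name: str) -> bool:
        return name in self.observations

    def items(self):
        return self.observations.items()


@dataclass
class PosteriorReport:
    """P(present) for every judgment factor, with the evidence echoed back."""

    posteriors: dict[str, float]
    evidence: dict[str, str]
    elimination_orders: dict[str, tuple[str, ...]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# factors


@dataclass
class _Factor:
    vars: tuple[str, ...]
    values: np.ndarray  # one axis per var, in order

    def marginalize(self, var: str) -> "_Factor":
        axis = self.vars.index(var)
        return _Factor(
            vars=self.vars[:axis] + self.vars[axis + 1 :],
            values=self.values.sum(axis=axis),
        )

    def reduce(self, var: str, state_index: int) -> "_Factor":
        axis = self.vars.index(var)
        return _Factor(
            vars=self.vars[:axis] + self.vars[axis + 1 :],
            values=np.take(self.values, state_index, axis=axis),
        )


def _multiply(f1: _Factor, f2: _Factor) -> _Factor:
    all_vars = f1.vars + tuple(v for v in f2.vars if v not in f1.vars)
    # broadcast both value arrays to the union scope
    a1 = _expand(f1, all_vars)
    a2 = _expand(f2, all_vars)
    return _Factor(vars=all_vars, values=a1 * a2)


def _expand(f: _Factor, all_vars: tuple[str, ...]) -> np.ndarray:
    if not f.vars:
        return f.values
    perm = sorted(range(len(f.vars)), key=lambda i: all_vars.index(f.vars[i]))
    arr = np.transpose(f.values, axes=perm)
    ordered = [f.vars[i] for i in perm]
    shape, j = [], 0
    for v in all_vars:
        if j < len(ordered) and ordered[j] == v:
            shape.append(arr.shape[j])
            j += 1
        else:
            shape.append(1)
    return arr.reshape(shape)


def _network_factors(pnet: ParameterizedNetwork, evidence: Evidence) -> list[_Factor]:
    """CPT factors with observed variables sliced out."""
    obs = evidence.observations
    factors: list[_Factor] = []
    for name in pnet.node_names():
        t = pnet.cpts[name]
        f = _Factor(vars=(name,) + t.parents, values=t.as_array())
        for var in f.vars:
            if var in obs:
                f = f.reduce(var, pnet.states(var).index(obs[var]))
        factors.append(f)
    return factors


def _min_fill_order(
    factors: list[_Factor], keep: set[str]
) -> tuple[str, ...]:
    """Min-fill elimination order with deterministic lexicographic tie-breaks."""
    neighbors: dict[str, set[str]] = {}
    for f in factors:
        for v in f.vars:
            neighbors.setdefault(v, set()).update(x for x in f.vars if x != v)
    to_eliminate = {v for v in neighbors if v not in keep}
    order = []
    while to_eliminate:
        best = None
        for v in sorted(to_eliminate):
            nb = [x for x in neighbors[v] if x in neighbors]
            fill = sum(
                1
                for a, b in itertools.combinations(nb, 2)
                if b not in neighbors[a]
            )
            if best is None or fill < best[0]:
                best = (fill, v)
        _, v = best
        nb = [x for x in neighbors[v] if x in neighbors]
        for a, b in itertools.combinations(nb, 2):
            neighbors[a].add(b)
            neighbors[b].add(a)
        for x in nb:
            neighbors[x].discard(v)
        del neighbors[v]
        to_eliminate.discard(v)
        order.append(v)
    return tuple(order)


def _eliminate(factors: list[_Factor], order: tuple[str, ...]) -> list[_Factor]:
    factors = list(factors)
    for var in order:
        related = [f for f in factors if var in f.vars]
        if not related:
            continue
        rest = [f for f in factors if var not in f.vars]
        prod = related[0]
        for f in related[1:]:
            prod = _multiply(prod, f)
        factors = rest + [prod.marginalize(var)]
    return factors


def query_posterior(
    pnet: ParameterizedNetwork, query: str, evidence: Evidence
) -> tuple[dict[str, float], tuple[str, ...]]:
    """Exact P(query | evidence) by variable elimination.

    Returns the posterior distribution over the query node's states and the
    elimination order used. Conditioning on the query node itself returns a
    point mass on the observed state.
    """
    evidence.validate(pnet)
    if not pnet.net.has_node(query):
        raise EvidenceError(f"query names unknown node {query!r}")
    states = pnet.states(query)
    if query in evidence:
        obs = evidence.observations[query]
        return {s: 1.0 if s == obs else 0.0 for s in states}, ()

    factors = _network_factors(pnet, evidence)
    order = _min_fill_order(factors, keep={query})
    remaining = _eliminate(factors, order)
    result = _Factor(vars=(query,), values=np.ones(len(states)))
    for f in remaining:
        result = _multiply(result, f)
    values = result.values.reshape(-1)
    total = values.sum()
    if total <= 0:
        raise ZeroDivisionError(
            f"evidence has probability zero; posterior of {query!r} undefined"
        )
    values = values / total
    return {s: float(values[i]) for i, s in enumerate(states)}, order


def posterior_judgments(
    pnet: ParameterizedNetwork, evidence: Evidence
) -> PosteriorReport:
    """Exact P(present) for all judgment factors given partial evidence.

    Judgment factors must not themselves be observed (prediction mode);
    unknown risk and sign nodes are marginalized.
    """
    evidence.validate(pnet)
    judgments = pnet.net.judgment_names()
    for name in judgments:
        if name in evidence:
            raise EvidenceError(
                f"judgment factor {name!r} cannot be evidence in prediction mode"
            )
    posteriors = {}
    orders = {}
    for name in judgments:
        dist, order = query_posterior(pnet, name, evidence)
        posteriors[name] = dist["present"]
        orders[name] = order
    return PosteriorReport(
        posteriors=posteriors,
        evidence=dict(evidence.observations),
        elimination_orders=orders,
    )


def brute_force_posterior(
    pnet: ParameterizedNetwork, query: str, evidence: Evidence
) -> dict[str, float]:
    """Reference posterior by summing the full joint; guarded to small networks."""
    names = pnet.node_names()
    if len(names) > BRUTE_FORCE_MAX_NODES:
        raise ValueError(
            f"brute-force enumeration limited to {BRUTE_FORCE_MAX_NODES} nodes, "
            f"network has {len(names)}"
        )
    evidence.validate(pnet)
    if not pnet.net.has_node(query):
        raise EvidenceError(f"query names unknown node {query!r}")
    obs = evidence.observations
    state_lists = [pnet.states(n) for n in names]
    q_idx = names.index(query)
    totals = {s: 0.0 for s in state_lists[q_idx]}
    for assignment in itertools.product(*state_lists):
        world = dict(zip(names, assignment))
        if any(world[k] != v for k, v in obs.items()):
            continue
        p = 1.0
        for n in names:
            t = pnet.cpts[n]
            combo = tuple(world[par] for par in t.parents)
            p *= t.rows[combo][t.child_states.index(world[n])]
        totals[assignment[q_idx]] += p
    z = sum(totals.values())
    if z <= 0:
        raise ZeroDivisionError("evidence has probability zero")
    return {s: v / z for s, v in totals.items()}


__all__ = [
    "BRUTE_FORCE_MAX_NODES",
    "EvidenceError",
    "Evidence",
    "PosteriorReport",
    "query_posterior",
    "posterior_judgments",
    "brute_force_posterior",
]
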