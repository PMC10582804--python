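"""Probability parameterization: root priors plus conditional tables.

Conditional tables for multi-parent nodes are completed from per-edge link
strengths with a *leaky noisy-OR* model: each active (present) parent
independently triggers the child with its link strength, and a background
"leak" captures all causes outside the model,

    P(child = present | active set A) = 1 - (1 - leak) * prod_{i in A} (1 - s_i).

One number per edge plus a leak is exactly the granularity a scenario-based
expert elicitation produces, which is why the model is standard for
expert-built cause->effect networks. The elicited probabilities behind the
published SSP model are not public, so this module also draws documented,
seeded synthetic parameter sets for testing and demonstration.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .network import NetworkDefinition, StructureError

#: Map from elicited 0-3 relationship strengths to default link probabilities.
ELICITED_STRENGTH_MAP = {0: 0.0, 1: 0.3, 2: 0.6, 3: 0.85}

ROW_SUM_TOL = 1e-9


class SpecificationError(ValueError):
    """A parameter specification does not match the network it targets."""


@dataclass(frozen=True)
class NoisyOrSpec:
    """Leaky noisy-OR parameters for one child: a leak plus one strength per parent."""

    child: str
    leak: float
    link_strength: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.leak < 1.0:
            raise SpecificationError(
                f"{self.child}: leak must be in [0, 1), got {self.leak}"
            )
        for parent, s in self.link_strength.items():
            if not 0.0 <= s <= 1.0:
                raise SpecificationError(
                    f"{self.child}: strength for {parent!r} out of [0, 1]: {s}"
                )


@dataclass
class ConditionalTable:
    """Explicit CPT: one distribution over child states per parent-state combination."""

    child: str
    parents: tuple[str, ...]
    child_states: tuple[str, ...]
    parent_states: tuple[tuple[str, ...], ...]
    rows: dict[tuple[str, ...], tuple[float, ...]]

    def validate(self) -> None:
        expected = set(itertools.product(*self.parent_states)) if self.parents else {()}
        got = set(self.rows)
        if got != expected:
            raise SpecificationError(
                f"{self.child}: rows cover {len(got)} combinations, "
                f"expected {len(expected)}"
            )
        for combo, dist in self.rows.items():
            if len(dist) != len(self.child_states):
                raise SpecificationError(f"{self.child}: row {combo} wrong arity")
            if any(p < 0 for p in dist):
                raise SpecificationError(f"{self.child}: negative probability in {combo}")
            if abs(sum(dist) - 1.0) > ROW_SUM_TOL:
                raise SpecificationError(
                    f"{self.child}: row {combo} sums to {sum(dist)!r}, not 1"
                )

    def as_array(self) -> np.ndarray:
        """CPT as array indexed [child_state, parent1_state, parent2_state, ...]."""
        shape = (len(self.child_states),) + tuple(len(s) for s in self.parent_states)
        arr = np.empty(shape)
        for combo, dist in self.rows.items():
            idx = tuple(
                self.parent_states[i].index(combo[i]) for i in range(len(self.parents))
            )
            for k, p in enumerate(dist):
                arr[(k,) + idx] = p
        return arr


@dataclass
class ParameterSet:
    """Root priors (P(present)) plus one table or noisy-OR spec per non-root node."""

    priors: dict[str, float] = field(default_factory=dict)
    tables: dict[str, "ConditionalTable | NoisyOrSpec"] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out: dict = {"priors": dict(self.priors), "tables": {}}
        for name, t in self.tables.items():
            if isinstance(t, NoisyOrSpec):
                out["tables"][name] = {
                    "kind": "noisy_or",
                    "leak": t.leak,
                    "link_strength": dict(t.link_strength),
                }
            else:
                out["tables"][name] = {
                    "kind": "table",
                    "parents": list(t.parents),
                    "child_states": list(t.child_states),
                    "parent_states": [list(s) for s in t.parent_states],
                    "rows": [
                        {"combo": list(c), "dist": list(d)} for c, d in t.rows.items()
                    ],
                }
        return out

    @classmethod
    def from_dict(cls, doc: dict) -> "ParameterSet":
        ps = cls(priors={k: float(v) for k, v in doc.get("priors", {}).items()})
        for name, td in doc.get("tables", {}).items():
            if td.get("kind") == "noisy_or":
                ps.tables[name] = NoisyOrSpec(
                    child=name,
                    leak=float(td["leak"]),
                    link_strength={k: float(v) for k, v in td["link_strength"].items()},
                )
            else:
                ps.tables[name] = ConditionalTable(
                    child=name,
                    parents=tuple(td["parents"]),
                    child_states=tuple(td["child_states"]),
                    parent_states=tuple(tuple(s) for s in td["parent_states"]),
                    rows={
                        tuple(r["combo"]): tuple(float(x) for x in r["dist"])
                        for r in td["rows"]
                    },
                )
        return ps


def noisy_or_probability(leak: float, active_strengths) -> float:
    """Closed-form leaky noisy-OR: 1 - (1-leak) * prod(1 - s_i) over active parents."""
    q = 1.0 - leak
    for s in active_strengths:
        q *= 1.0 - s
    return 1.0 - q


def noisy_or_table(spec: NoisyOrSpec, net: NetworkDefinition) -> ConditionalTable:
    """Expand a noisy-OR spec to an explicit CPT over the child's parents in ``net``.

    Parents must be binary with states including "present"; the active set of
    a row is the set of parents in the "present" state.
    """
    parents = tuple(net.parents(spec.child))
    have = set(spec.link_strength)
    want = set(parents)
    if have != want:
        missing = sorted(want - have)
        extra = sorted(have - want)
        raise SpecificationError(
            f"{spec.child}: noisy-OR strengths mismatch network parents"
            + (f"; missing {missing}" if missing else "")
            + (f"; extra {extra}" if extra else "")
        )
    child_states = net.node(spec.child).states
    if "present" not in child_states or "absent" not in child_states:
        raise SpecificationError(f"{spec.child}: noisy-OR requires present/absent states")
    parent_states = tuple(net.node(p).states for p in parents)
    rows = {}
    for combo in itertools.product(*parent_states) if parents else [()]:
        active = [
            spec.link_strength[p]
            for p, st in zip(parents, combo)
            if st == "present"
        ]
        p_present = noisy_or_probability(spec.leak, active)
        dist = tuple(
            p_present if s == "present" else (1.0 - p_present) if s == "absent" else 0.0
            for s in child_states
        )
        rows[combo] = dist
    table = ConditionalTable(
        child=spec.child,
        parents=parents,
        child_states=child_states,
        parent_states=parent_states,
        rows=rows,
    )
    table.validate()
    return table


def strength_from_elicited(score: int) -> float:
    return ELICITED_STRENGTH_MAP[score]


def random_parameterization(
    net: NetworkDefinition,
    seed: int,
    *,
    risk_prior: tuple[float, float] = (0.05, 0.4),
    judgment_prior: tuple[float, float] = (0.01, 0.08),
    sign_prior: tuple[float, float] = (0.05, 0.3),
    judgment_leak: tuple[float, float] = (0.001, 0.02),
    sign_leak: tuple[float, float] = (0.01, 0.1),
    link: tuple[float, float] = (0.2, 0.9),
    judgment_marginal_target: tuple[float, float] | None = None,
) -> ParameterSet:
    """Draw a seeded synthetic parameter set from documented uniform ranges.

    If ``judgment_marginal_target`` is given, each judgment node's leak and
    incoming link strengths are calibrated (uniform rescaling, Brent root
    finding on the noisy-OR marginal) so its no-evidence marginal of
    "present" equals a value drawn from that range — keeping the pathology
    baseline rates rare regardless of how many risk parents the node has.
    Deterministic under ``seed``; node order follows the network definition.
    """
    rng = np.random.default_rng(seed)
    params = ParameterSet()

    prior_range = {
        "risk_factor": risk_prior,
        "judgment_factor": judgment_prior,
        "sign_symptom": sign_prior,
    }
    leak_range = {"judgment_factor": judgment_leak, "sign_symptom": sign_leak}

    # roots first: judgment calibration needs its parents' priors in hand
    for node in net.nodes:
        if not net.parents(node.name):
            lo, hi = prior_range[node.layer]
            params.priors[node.name] = float(rng.uniform(lo, hi))
    for node in net.nodes:
        parents = net.parents(node.name)
        if not parents:
            continue
        lo, hi = leak_range.get(node.layer, sign_leak)
        leak = float(rng.uniform(lo, hi))
        strengths = {}
        for p in parents:
            edge = next(
                e for e in net.edges if e.parent == p and e.child == node.name
            )
            if edge.elicited_strength is not None:
                strengths[p] = strength_from_elicited(edge.elicited_strength)
            else:
                strengths[p] = float(rng.uniform(*link))
        if node.layer == "judgment_factor" and judgment_marginal_target is not None:
            target = float(rng.uniform(*judgment_marginal_target))
            leak, strengths = _calibrate_judgment(
                target, strengths, {p: params.priors[p] for p in parents}
            )
        params.tables[node.name] = NoisyOrSpec(
            child=node.name, leak=leak, link_strength=strengths
        )
    return params


def _calibrate_judgment(
    target: float, strengths: dict[str, float], parent_priors: dict[str, float]
) -> tuple[float, dict[str, float]]:
    """Rescale link strengths so the noisy-OR marginal hits ``target``.

    Valid when the node's parents are independent roots (true in the
    three-layer structure: risk factors have no parents). The leak is set to
    half the target; the remaining half of the marginal is distributed over
    the parents by a common scale factor alpha in (0, 1].
    """
    leak = target / 2.0

    def marginal(alpha: float) -> float:
        q = 1.0 - leak
        for p, s in strengths.items():
            q *= 1.0 - parent_priors[p] * alpha * s
        return 1.0 - q

    if marginal(1.0) <= target:
        alpha = 1.0
    else:
        alpha = brentq(lambda a: marginal(a) - target, 0.0, 1.0, xtol=1e-12)
    return leak, {p: s * alpha for p, s in strengths.items()}


def default_parameterization(net: NetworkDefinition, seed: int) -> ParameterSet:
    """Seeded default parameter set with rare judgment-factor baselines.

    Serious spinal pathologies are rare, so every judgment node's
    no-evidence marginal of "present" is calibrated into [0.01, 0.08]
    (hence always <= 0.1); sign and risk parameters come from the
    documented uniform ranges of :func:`random_parameterization`.
    """
    return random_parameterization(
        net, seed, judgment_marginal_target=(0.01, 0.08)
    )


@dataclass
class ParameterizedNetwork:
    """A network with every node carrying an explicit, validated CPT.

    ``cpts`` maps every node name to a ConditionalTable (root nodes get a
    parentless table built from their prior), ready for exact inference.
    """

    net: NetworkDefinition
    cpts: dict[str, ConditionalTable]

    def states(self, name: str) -> tuple[str, ...]:
        return self.net.node(name).states

    def node_names(self) -> list[str]:
        return self.net.node_names()


def attach_parameters(
    net: NetworkDefinition, params: ParameterSet
) -> ParameterizedNetwork:
    """Bind a ParameterSet to a structure, expanding noisy-OR specs to tables.

    Raises SpecificationError naming missing or extra nodes if the coverage
    does not match the structure exactly, and propagates row-sum violations.
    """
    roots = [n.name for n in net.nodes if not net.parents(n.name)]
    non_roots = [n.name for n in net.nodes if net.parents(n.name)]

    missing_priors = sorted(set(roots) - set(params.priors))
    missing_tables = sorted(set(non_roots) - set(params.tables))
    extra = sorted(
        (set(params.priors) - set(roots)) | (set(params.tables) - set(non_roots))
    )
    problems = []
    if missing_priors:
        problems.append(f"missing priors for root nodes: {missing_priors}")
    if missing_tables:
        problems.append(f"missing tables for nodes: {missing_tables}")
    if extra:
        problems.append(f"parameters for unexpected nodes: {extra}")
    if problems:
        raise SpecificationError("; ".join(problems))

    cpts: dict[str, ConditionalTable] = {}
    for name in roots:
        prior = params.priors[name]
        if not 0.0 < prior < 1.0:
            raise SpecificationError(f"{name}: root prior must be in (0, 1), got {prior}")
        states = net.node(name).states
        dist = tuple(
            prior if s == "present" else (1.0 - prior) if s == "absent" else 0.0
            for s in states
        )
        cpts[name] = ConditionalTable(
            child=name,
            parents=(),
            child_states=states,
            parent_states=(),
            rows={(): dist},
        )
        cpts[name].validate()
    for name in non_roots:
        t = params.tables[name]
        if isinstance(t, NoisyOrSpec):
            cpts[name] = noisy_or_table(t, net)
        else:
            expected_parents = tuple(net.parents(name))
            if tuple(t.parents) != expected_parents:
                if set(t.parents) == set(expected_parents):
                    # reorder columns to the network's canonical parent order
                    perm = [t.parents.index(p) for p in expected_parents]
                    t = ConditionalTable(
                        child=name,
                        parents=expected_parents,
                        child_states=t.child_states,
                        parent_states=tuple(t.parent_states[i] for i in perm),
                        rows={
                            tuple(c[i] for i in perm): d for c, d in t.rows.items()
                        },
                    )
                else:
                    raise SpecificationError(
                        f"{name}: table parents {t.parents} != network parents "
                        f"{expected_parents}"
                    )
            t.validate()
            cpts[name] = t
    return ParameterizedNetwork(net=net, cpts=cpts)


def build_default_model(seed: int = 0) -> ParameterizedNetwork:
    """Convenience: packaged structure + seeded default parameterization."""
    from .network import build_default_network

    net = build_default_network()
    return attach_parameters(net, default_parameterization(net, seed))


__all__ = [
    "ELICITED_STRENGTH_MAP",
    "SpecificationError",
    "NoisyOrSpec",
    "ConditionalTable",
    "ParameterSet",
    "ParameterizedNetwork",
    "noisy_or_probability",
    "noisy_or_table",
    "strength_from_elicited",
    "random_parameterization",
    "default_parameterization",
    "attach_parameters",
    "build_default_model",
]
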