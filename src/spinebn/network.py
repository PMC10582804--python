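"""Layered causal network structure for serious spinal pathology (SSP) screening.

The model is a three-layer directed acyclic graph: antecedent *risk factors*
(patient history items such as trauma or steroid use) point into *judgment
factors* (the candidate pathologies — deliberately not called diagnoses), and
judgment factors point into the *signs and symptoms* a clinician can observe.
Every node and edge carries a provenance tag recording which published source
element it was reconstructed from; elements that cannot be recovered from any
source are tagged ``placeholder`` and must explain why.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx

LAYERS = ("risk_factor", "judgment_factor", "sign_symptom")
PROVENANCE_TAGS = ("table3", "results_text", "figure6_caption", "placeholder")

#: Allowed parent-layer -> child-layer pairs. Edges only ever descend one layer.
LAYER_ORDER = {
    ("risk_factor", "judgment_factor"),
    ("judgment_factor", "sign_symptom"),
}

DEFAULT_STATES = ("present", "absent")


class StructureError(ValueError):
    """A network definition violates a structural invariant."""


@dataclass(frozen=True)
class VariableNode:
    """A clinical variable in one of the three reasoning layers.

    States default to binary present/absent. ``unknown`` is never a state:
    it is an evidence condition (the node is simply not observed).
    """

    name: str
    layer: str
    states: tuple[str, ...] = DEFAULT_STATES
    display_name: str = ""
    description: str = ""
    provenance: str = "placeholder"

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise StructureError(f"node {self.name!r}: unknown layer {self.layer!r}")
        if self.provenance not in PROVENANCE_TAGS:
            raise StructureError(
                f"node {self.name!r}: unknown provenance {self.provenance!r}"
            )
        if len(set(self.states)) < 2:
            raise StructureError(f"node {self.name!r}: needs >=2 distinct states")
        if "unknown" in self.states:
            raise StructureError(
                f"node {self.name!r}: 'unknown' is an evidence condition, not a state"
            )
        if self.provenance == "placeholder" and not self.description:
            raise StructureError(
                f"node {self.name!r}: placeholder nodes must carry a description"
            )
        if not self.display_name:
            object.__setattr__(
                self, "display_name", self.name.replace("_", " ").capitalize()
            )


@dataclass(frozen=True)
class DirectedEdge:
    """A causal arrow between layers, optionally carrying its elicited 0-3 strength."""

    parent: str
    child: str
    elicited_strength: int | None = None
    provenance: str = "placeholder"
    note: str = ""

    def __post_init__(self) -> None:
        if self.parent == self.child:
            raise StructureError(f"self-loop on {self.parent!r}")
        if self.provenance not in PROVENANCE_TAGS:
            raise StructureError(
                f"edge {self.parent}->{self.child}: unknown provenance"
            )
        if self.elicited_strength is not None and self.elicited_strength not in (
            0,
            1,
            2,
            3,
        ):
            raise StructureError(
                f"edge {self.parent}->{self.child}: elicited strength must be 0-3"
            )


@dataclass
class NetworkDefinition:
    """Nodes plus edges plus free-form metadata; validated lazily by reports."""

    nodes: list[VariableNode] = field(default_factory=list)
    edges: list[DirectedEdge] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    # -- lookups ---------------------------------------------------------
    def node(self, name: str) -> VariableNode:
        for n in self.nodes:
            if n.name == name:
                return n
        raise KeyError(name)

    def node_names(self) -> list[str]:
        return [n.name for n in self.nodes]

    def has_node(self, name: str) -> bool:
        return any(n.name == name for n in self.nodes)

    def parents(self, name: str) -> list[str]:
        return [e.parent for e in self.edges if e.child == name]

    def children(self, name: str) -> list[str]:
        return [e.child for e in self.edges if e.parent == name]

    def layer_nodes(self, layer: str) -> list[VariableNode]:
        return [n for n in self.nodes if n.layer == layer]

    def layer_counts(self) -> dict[str, int]:
        return {layer: len(self.layer_nodes(layer)) for layer in LAYERS}

    def judgment_names(self) -> list[str]:
        return [n.name for n in self.layer_nodes("judgment_factor")]

    def to_digraph(self) -> "nx.DiGraph":
        g = nx.DiGraph()
        g.add_nodes_from(self.node_names())
        g.add_edges_from((e.parent, e.child) for e in self.edges)
        return g

    # -- (de)serialization ----------------------------------------------
    def to_dict(self) -> dict:
        return {
            "metadata": dict(self.metadata),
            "nodes": [
                {
                    "name": n.name,
                    "layer": n.layer,
                    "states": list(n.states),
                    "display_name": n.display_name,
                    "description": n.description,
                    "provenance": n.provenance,
                }
                for n in self.nodes
            ],
            "edges": [
                {
                    "parent": e.parent,
                    "child": e.child,
                    "elicited_strength": e.elicited_strength,
                    "provenance": e.provenance,
                    "note": e.note,
                }
                for e in self.edges
            ],
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "NetworkDefinition":
        if not isinstance(doc, dict):
            raise StructureError("network document must be a mapping")
        nodes = []
        for i, nd in enumerate(doc.get("nodes", [])):
            for key in ("name", "layer"):
                if key not in nd:
                    raise StructureError(
                        f"node #{i} ({nd.get('name', '?')!r}): missing field {key!r}"
                    )
            nodes.append(
                VariableNode(
                    name=nd["name"],
                    layer=nd["layer"],
                    states=tuple(nd.get("states", DEFAULT_STATES)),
                    display_name=nd.get("display_name", ""),
                    description=nd.get("description", ""),
                    provenance=nd.get("provenance", "placeholder"),
                )
            )
        edges = []
        for i, ed in enumerate(doc.get("edges", [])):
            for key in ("parent", "child"):
                if key not in ed:
                    raise StructureError(f"edge #{i}: missing field {key!r}")
            edges.append(
                DirectedEdge(
                    parent=ed["parent"],
                    child=ed["child"],
                    elicited_strength=ed.get("elicited_strength"),
                    provenance=ed.get("provenance", "placeholder"),
                    note=ed.get("note", ""),
                )
            )
        return cls(nodes=nodes, edges=edges, metadata=doc.get("metadata", {}))


@dataclass
class StructureReport:
    """Outcome of structural validation; violations are listed, never thrown."""

    layer_counts: dict[str, int]
    acyclic: bool
    layer_order_violations: list[str]
    dangling_edges: list[str]
    duplicate_names: list[str]

    @property
    def ok(self) -> bool:
        return (
            self.acyclic
            and not self.layer_order_violations
            and not self.dangling_edges
            and not self.duplicate_names
        )


@dataclass
class ProvenanceSummary:
    node_counts: dict[str, int]
    edge_counts: dict[str, int]
    placeholder_nodes: list[str]
    placeholder_edges: list[tuple[str, str]]

    @property
    def placeholder_count(self) -> int:
        return len(self.placeholder_nodes) + len(self.placeholder_edges)


def validate_structure(net: NetworkDefinition) -> StructureReport:
    """Check layer counts, acyclicity, layer ordering, dangling endpoints, duplicates."""
    names = net.node_names()
    seen: set[str] = set()
    duplicates = sorted({n for n in names if n in seen or seen.add(n)})

    layer_of = {n.name: n.layer for n in net.nodes}
    order_violations = []
    dangling = []
    for e in net.edges:
        missing = [x for x in (e.parent, e.child) if x not in layer_of]
        if missing:
            dangling.append(f"{e.parent}->{e.child}: unknown {', '.join(missing)}")
            continue
        if (layer_of[e.parent], layer_of[e.child]) not in LAYER_ORDER:
            order_violations.append(
                f"{e.parent}({layer_of[e.parent]})->{e.child}({layer_of[e.child]})"
            )

    # Layer ordering already forbids cycles, but check independently via DFS.
    g = nx.DiGraph()
    g.add_nodes_from(names)
    g.add_edges_from(
        (e.parent, e.child)
        for e in net.edges
        if e.parent in layer_of and e.child in layer_of
    )
    acyclic = nx.is_directed_acyclic_graph(g)

    return StructureReport(
        layer_counts=net.layer_counts(),
        acyclic=acyclic,
        layer_order_violations=order_violations,
        dangling_edges=dangling,
        duplicate_names=duplicates,
    )


def provenance_report(net: NetworkDefinition) -> ProvenanceSummary:
    """Tally nodes and edges per provenance tag; list every placeholder element."""
    node_counts = {tag: 0 for tag in PROVENANCE_TAGS}
    edge_counts = {tag: 0 for tag in PROVENANCE_TAGS}
    for n in net.nodes:
        node_counts[n.provenance] += 1
    for e in net.edges:
        edge_counts[e.provenance] += 1
    return ProvenanceSummary(
        node_counts=node_counts,
        edge_counts=edge_counts,
        placeholder_nodes=[n.name for n in net.nodes if n.provenance == "placeholder"],
        placeholder_edges=[
            (e.parent, e.child) for e in net.edges if e.provenance == "placeholder"
        ],
    )


def build_default_network() -> NetworkDefinition:
    """Load the packaged default SSP structure (38 nodes: 10 risk, 11 judgment, 17 signs)."""
    from .io import load_packaged_network

    return load_packaged_network()


__all__ = [
    "LAYERS",
    "PROVENANCE_TAGS",
    "DEFAULT_STATES",
    "StructureError",
    "VariableNode",
    "DirectedEdge",
    "NetworkDefinition",
    "StructureReport",
    "ProvenanceSummary",
    "validate_structure",
    "provenance_report",
    "build_default_network",
    "replace",
]
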