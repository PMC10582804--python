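"""Readers and writers for networks, parameters, cases, ratings, agreement tables.

Networks and parameter sets are JSON documents (YAML accepted as an
equivalent dialect on read, chosen by file extension). Cases, ratings and
agreement tables travel as CSV. Evidence strings are case-insensitive on
read and canonical lower-case on write; probabilities in tabular output are
printed with 6 decimal places.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .consensus import RatingMatrix
from .inference import Evidence
from .network import NetworkDefinition, StructureError
from .parameters import ParameterSet
from .validation import AgreementTable, CaseRecord, PREDICTABLE_CONDITIONS, LabelError

_EVIDENCE_VALUES = {"present", "absent", "unknown"}


class ParseError(ValueError):
    """A document failed to parse or violated its schema."""


def _load_document(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix.lower() in (".yaml", ".yml"):
            return yaml.safe_load(text)
        return json.loads(text)
    except (json.JSONDecodeError, yaml.YAMLError) as err:
        raise ParseError(f"{path}: {err}") from err


def read_network(path: str | Path) -> NetworkDefinition:
    doc = _load_document(path)
    try:
        return NetworkDefinition.from_dict(doc)
    except StructureError as err:
        raise ParseError(f"{path}: {err}") from err


def write_network(net: NetworkDefinition, path: str | Path) -> None:
    path = Path(path)
    doc = net.to_dict()
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
    else:
        path.write_text(json.dumps(doc, indent=2) + "\n")


def read_parameters(path: str | Path) -> ParameterSet:
    return ParameterSet.from_dict(_load_document(path))


def write_parameters(params: ParameterSet, path: str | Path) -> None:
    Path(path).write_text(json.dumps(params.to_dict(), indent=2) + "\n")


# ---------------------------------------------------------------------------
# packaged data


def _packaged(name: str) -> dict:
    with resources.files("spinebn.data").joinpath(name).open() as fh:
        return json.load(fh)


def load_packaged_network() -> NetworkDefinition:
    return NetworkDefinition.from_dict(_packaged("default_network.json"))


def load_containment_reference() -> dict[str, list[dict]]:
    """Published red-flag factor lists per condition, with node aliases."""
    return _packaged("containment_reference.json")


def load_judgment_agreement() -> dict[str, float]:
    """Published content-validation agreement coefficients per judgment factor."""
    return {k: float(v) for k, v in _packaged("judgment_agreement.json").items()}


def load_packaged_framework() -> list[dict]:
    return _packaged("validation_framework.json")


def load_case_inventory() -> list[dict]:
    """The published predictive-validation case inventory (names, sources,
    sensitivity variations); the codified evidence itself is not public."""
    return _packaged("case_inventory.json")


# ---------------------------------------------------------------------------
# cases


def _parse_evidence_value(raw, where: str) -> str:
    value = str(raw).strip().lower()
    if value in ("", "nan", "none"):
        return "unknown"
    if value not in _EVIDENCE_VALUES:
        raise ParseError(f"{where}: evidence value {raw!r} not in {_EVIDENCE_VALUES}")
    return value


def read_cases(path: str | Path, net: NetworkDefinition) -> list[CaseRecord]:
    """Load cases from CSV (wide) or JSON; unknown evidence is omitted.

    CSV columns: id, optional source, one column per non-judgment node with
    values present/absent/unknown (case-insensitive), label_<condition>
    columns with 0/1. JSON: list of {id, evidence: {node: value},
    labels: {condition: 0/1}, source}.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        docs = _load_document(path)
        cases = []
        for i, d in enumerate(docs or []):
            obs = {}
            for node, raw in d.get("evidence", {}).items():
                if not net.has_node(node):
                    raise ParseError(f"{path} case #{i}: unknown node {node!r}")
                value = _parse_evidence_value(raw, f"{path} case #{i}")
                if value != "unknown":
                    obs[node] = value
            try:
                cases.append(
                    CaseRecord(
                        id=str(d.get("id", f"case_{i}")),
                        evidence=Evidence(obs),
                        labels={k: int(v) for k, v in d.get("labels", {}).items()},
                        source=d.get("source", "file"),
                    )
                )
            except LabelError as err:
                raise ParseError(f"{path} case #{i}: {err}") from err
        return cases

    frame = pd.read_csv(path)
    if frame.empty:
        return []
    cases = []
    label_prefix = "label_"
    for i, row in frame.iterrows():
        where = f"{path} row {i + 2}"  # 1-based plus header
        obs = {}
        labels = {}
        for col in frame.columns:
            if col in ("id", "source"):
                continue
            if col.startswith(label_prefix):
                condition = col[len(label_prefix) :]
                if condition not in PREDICTABLE_CONDITIONS:
                    raise ParseError(
                        f"{where}: label column for non-predictable condition "
                        f"{condition!r}"
                    )
                if not pd.isna(row[col]):
                    value = int(row[col])
                    if value not in (0, 1):
                        raise ParseError(f"{where}: label {condition}={row[col]!r}")
                    labels[condition] = value
                continue
            if not net.has_node(col):
                raise ParseError(f"{where}: unknown node column {col!r}")
            value = _parse_evidence_value(row[col], where)
            if value != "unknown":
                obs[col] = value
        cases.append(
            CaseRecord(
                id=str(row.get("id", f"case_{i}")),
                evidence=Evidence(obs),
                labels=labels,
                source=str(row.get("source", "file")),
            )
        )
    return cases


def write_cases(cases: list[CaseRecord], net: NetworkDefinition, path: str | Path) -> None:
    from .simulate import cases_to_frame

    cases_to_frame(cases, net).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ratings and agreement tables


def read_ratings(path: str | Path) -> RatingMatrix:
    """Ratings CSV: wide (participant rows x item columns, first column
    'participant') or long (participant,item,score)."""
    frame = pd.read_csv(path)
    cols = [c.lower() for c in frame.columns]
    if {"participant", "item", "score"}.issubset(cols):
        frame.columns = cols
        wide = frame.pivot_table(
            index="item", columns="participant", values="score", aggfunc="first"
        )
        return RatingMatrix(scores=wide)
    first = frame.columns[0]
    frame = frame.set_index(first)
    # wide file is participants x items; store as items x participants
    return RatingMatrix(scores=frame.T)


def read_agreement(path: str | Path) -> AgreementTable:
    """Agreement CSV, long form: item, rater, category."""
    frame = pd.read_csv(path)
    frame.columns = [c.lower() for c in frame.columns]
    required = {"item", "rater", "category"}
    if not required.issubset(frame.columns):
        raise ParseError(f"{path}: agreement CSV needs columns {sorted(required)}")
    wide = frame.pivot_table(
        index="item", columns="rater", values="category", aggfunc="first"
    )
    return AgreementTable(ratings=wide)


__all__ = [
    "ParseError",
    "read_network",
    "write_network",
    "read_parameters",
    "write_parameters",
    "load_packaged_network",
    "load_containment_reference",
    "load_judgment_agreement",
    "load_packaged_framework",
    "load_case_inventory",
    "read_cases",
    "write_cases",
    "read_ratings",
    "read_agreement",
]
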