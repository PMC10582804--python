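import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spinebn.inference import Evidence, query_posterior
from spinebn.network import DirectedEdge, NetworkDefinition, VariableNode
from spinebn.parameters import (
    ConditionalTable,
    NoisyOrSpec,
    ParameterSet,
    SpecificationError,
    attach_parameters,
    default_parameterization,
    noisy_or_probability,
    noisy_or_table,
)


def two_parent_net():
    return NetworkDefinition(
        nodes=[
            VariableNode("a", "risk_factor", provenance="table3"),
            VariableNode("b", "risk_factor", provenance="table3"),
            VariableNode("j", "judgment_factor", provenance="table3"),
        ],
        edges=[
            DirectedEdge("a", "j", provenance="table3"),
            DirectedEdge("b", "j", provenance="table3"),
        ],
    )


class TestNoisyOr:
    def test_leak_only_row(self):
        net = two_parent_net()
        table = noisy_or_table(NoisyOrSpec("j", 0.1, {"a": 0.8, "b": 0.5}), net)
        row = table.rows[("absent", "absent")]
        assert row[table.child_states.index("present")] == pytest.approx(0.1)

    def test_both_active(self):
        net = two_parent_net()
        table = noisy_or_table(NoisyOrSpec("j", 0.1, {"a": 0.8, "b": 0.5}), net)
        row = table.rows[("present", "present")]
        # 1 - 0.9 * 0.2 * 0.5
        assert row[table.child_states.index("present")] == pytest.approx(0.91)

    def test_rows_sum_to_one(self):
        net = two_parent_net()
        table = noisy_or_table(NoisyOrSpec("j", 0.3, {"a": 0.2, "b": 0.9}), net)
        for dist in table.rows.values():
            assert sum(dist) == pytest.approx(1.0, abs=1e-12)

    def test_missing_parent_strength_rejected(self):
        net = two_parent_net()
        with pytest.raises(SpecificationError, match="missing"):
            noisy_or_table(NoisyOrSpec("j", 0.1, {"a": 0.8}), net)

    def test_extra_parent_strength_rejected(self):
        net = two_parent_net()
        with pytest.raises(SpecificationError, match="extra"):
            noisy_or_table(NoisyOrSpec("j", 0.1, {"a": 0.8, "b": 0.5, "c": 0.1}), net)

    def test_leak_at_least_one_rejected(self):
        with pytest.raises(SpecificationError):
            NoisyOrSpec("j", 1.0, {})

    @given(
        leak=st.floats(0, 0.99),
        s_a=st.floats(0, 1),
        s_b=st.floats(0, 1),
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_monotone_in_active_set(self, leak, s_a, s_b):
        """Activating an extra cause never lowers P(present)."""
        p_none = noisy_or_probability(leak, [])
        p_a = noisy_or_probability(leak, [s_a])
        p_ab = noisy_or_probability(leak, [s_a, s_b])
        assert p_none <= p_a + 1e-12
        assert p_a <= p_ab + 1e-12

    def test_zero_strength_parent_has_no_effect(self):
        net = two_parent_net()
        table = noisy_or_table(NoisyOrSpec("j", 0.2, {"a": 0.0, "b": 0.6}), net)
        for b_state in ("present", "absent"):
            assert table.rows[("present", b_state)] == pytest.approx(
                table.rows[("absent", b_state)]
            )

    def test_expansion_matches_closed_form(self):
        net = two_parent_net()
        spec = NoisyOrSpec("j", 0.07, {"a": 0.33, "b": 0.66})
        table = noisy_or_table(spec, net)
        for combo in itertools.product(("present", "absent"), repeat=2):
            active = [
                spec.link_strength[p]
                for p, s in zip(("a", "b"), combo)
                if s == "present"
            ]
            expected = noisy_or_probability(spec.leak, active)
            assert table.rows[combo][0] == pytest.approx(expected, abs=1e-12)


class TestDefaultParameterization:
    def test_deterministic_under_seed(self, default_net):
        p1 = default_parameterization(default_net, 42)
        p2 = default_parameterization(default_net, 42)
        assert p1.to_dict() == p2.to_dict()

    def test_seed_changes_values(self, default_net):
        p1 = default_parameterization(default_net, 1)
        p2 = default_parameterization(default_net, 2)
        assert p1.to_dict() != p2.to_dict()

    def test_complete_coverage(self, default_net):
        params = default_parameterization(default_net, 3)
        roots = {n.name for n in default_net.nodes if not default_net.parents(n.name)}
        non_roots = {n.name for n in default_net.nodes if default_net.parents(n.name)}
        assert set(params.priors) == roots
        assert set(params.tables) == non_roots

    @pytest.mark.parametrize("seed", [0, 7, 123])
    def test_judgment_marginals_rare(self, default_net, seed):
        """No-evidence P(present) of every judgment factor stays <= 0.1."""
        pnet = attach_parameters(default_net, default_parameterization(default_net, seed))
        for name in default_net.judgment_names():
            dist, _ = query_posterior(pnet, name, Evidence({}))
            assert dist["present"] <= 0.1

    def test_elicited_table3_links_positive(self, default_net):
        params = default_parameterization(default_net, 5)
        for edge in default_net.edges:
            if edge.provenance == "table3":
                spec = params.tables[edge.child]
                assert spec.link_strength[edge.parent] > 0


class TestAttachParameters:
    def test_happy_path(self, default_net):
        pnet = attach_parameters(default_net, default_parameterization(default_net, 0))
        assert set(pnet.cpts) == set(default_net.node_names())

    def test_missing_prior_named(self, default_net):
        params = default_parameterization(default_net, 0)
        del params.priors["trauma"]
        with pytest.raises(SpecificationError, match="trauma"):
            attach_parameters(default_net, params)

    def test_unnormalized_row_rejected(self):
        net = two_parent_net()
        bad = ConditionalTable(
            child="j",
            parents=("a", "b"),
            child_states=("present", "absent"),
            parent_states=(("present", "absent"), ("present", "absent")),
            rows={
                c: ((0.4, 0.5) if c == ("present", "present") else (0.5, 0.5))
                for c in itertools.product(("present", "absent"), repeat=2)
            },
        )
        params = ParameterSet(priors={"a": 0.1, "b": 0.2}, tables={"j": bad})
        with pytest.raises(SpecificationError, match="sums to"):
            attach_parameters(net, params)


def test_parameter_serialization_round_trip(default_net):
    params = default_parameterization(default_net, 9)
    doc = params.to_dict()
    again = ParameterSet.from_dict(doc)
    assert again.to_dict() == doc
    for name, spec in params.tables.items():
        other = again.tables[name]
        assert other.leak == spec.leak  # bit-for-bit through JSON-able floats
        assert other.link_strength == spec.link_strength


def test_json_text_round_trip_preserves_probabilities(default_net, tmp_path):
    import json

    from spinebn.io import read_parameters, write_parameters

    params = default_parameterization(default_net, 4)
    path = tmp_path / "params.json"
    write_parameters(params, path)
    again = read_parameters(path)
    assert again.to_dict() == params.to_dict()
    # decimal text carries >= 12 significant digits (repr round-trip)
    doc = json.loads(path.read_text())
    assert doc["priors"]["trauma"] == params.priors["trauma"]
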