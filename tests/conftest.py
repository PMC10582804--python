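import pytest

from spinebn.network import DirectedEdge, NetworkDefinition, VariableNode
from spinebn.parameters import NoisyOrSpec, ParameterSet, attach_parameters
from spinebn.simulate import (  # noqa: F401  (re-exported test helpers)
    random_evidence,
    random_layered_model as random_model,
)


@pytest.fixture(scope="session")
def default_net():
    from spinebn.network import build_default_network

    return build_default_network()


@pytest.fixture(scope="session")
def default_model(default_net):
    from spinebn.parameters import default_parameterization

    return attach_parameters(default_net, default_parameterization(default_net, 0))


def make_chain():
    """The 3-node chain risk -> judgment -> sign used as a hand oracle.

    P(r)=0.2; judgment noisy-OR leak 0.05, link 0.5; sign leak 0.1, link 0.8.
    Exact values: P(j)=0.145, P(j | s=present)=0.11890/0.20440.
    """
    net = NetworkDefinition(
        nodes=[
            VariableNode("r", "risk_factor", provenance="table3"),
            VariableNode("j", "judgment_factor", provenance="table3"),
            VariableNode("s", "sign_symptom", provenance="table3"),
        ],
        edges=[
            DirectedEdge("r", "j", provenance="table3"),
            DirectedEdge("j", "s", provenance="table3"),
        ],
    )
    params = ParameterSet(
        priors={"r": 0.2},
        tables={
            "j": NoisyOrSpec("j", 0.05, {"r": 0.5}),
            "s": NoisyOrSpec("s", 0.1, {"j": 0.8}),
        },
    )
    return attach_parameters(net, params)


@pytest.fixture
def chain_model():
    return make_chain()
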