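import pytest

from gynogrn.engine import NetworkModel, Not, Var


@pytest.fixture
def toggle_model():
    """The 2-node mutual-repression toggle {A = !B, B = !A}."""
    return NetworkModel(["A", "B"], {"A": Not(Var("B")), "B": Not(Var("A"))})


@pytest.fixture
def core_model():
    from gynogrn.grn import build_network
    return build_network("core_medial")
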