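import pytest

from intelligo import fixture_a, oracle_graph_stats


@pytest.fixture(scope="session")
def fixa():
    """The ten-term reference graph used by the worked examples."""
    return fixture_a()


@pytest.fixture(scope="session")
def fixa_oracle(fixa):
    """Exhaustive path-enumeration statistics for the reference graph."""
    return oracle_graph_stats(fixa)
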