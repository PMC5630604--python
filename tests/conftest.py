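import pytest

from commwalk import build_community_graph


@pytest.fixture(scope="session")
def graph():
    """Default 15-node, 3-community graph (shared; Hamiltonian enumeration
    cache warms once per session)."""
    return build_community_graph()


#: the worked 11-trial sequence used throughout (final node 5:
#: seen twice in the last 10 trials, last seen 5 trials ago)
WORKED_SEQUENCE = [1, 2, 5, 4, 3, 5, 3, 1, 3, 2, 5]
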