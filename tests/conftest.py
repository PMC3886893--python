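import pytest

import neurotraffic as nt


@pytest.fixture(scope="session")
def two_node_net():
    return nt.DirectedNetwork(["A", "B"], [("A", "B"), ("B", "A")])


@pytest.fixture(scope="session")
def three_node_complete():
    nodes = ["A", "B", "C"]
    edges = [(u, v) for u in nodes for v in nodes if u != v]
    return nt.DirectedNetwork(nodes, edges)


@pytest.fixture(scope="session")
def random20():
    """A 20-node strongly connected random directed graph."""
    net = nt.random_directed(20, 0.20, seed=3)
    assert nt.check_simulatable(net).strongly_connected
    return net


@pytest.fixture(scope="session")
def planted_richclub():
    """The planted rich-club study network (100 nodes, 20-node club,
    block densities 0.05 / 0.20 / 0.80)."""
    net, membership = nt.rich_club_synthetic(
        n=100, n_rc=20, p_local=0.05, p_feeder=0.20, p_rich=0.80, seed=42)
    return net, membership
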