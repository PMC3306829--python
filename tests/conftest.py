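import numpy as np
import pytest

from interolink import FixtureSpec, InteractionNetwork, plant_interaction_scenario


@pytest.fixture(scope="session")
def bundle():
    """One deterministic planted scenario shared across the suite."""
    return plant_interaction_scenario(FixtureSpec(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_network(rng, n_nodes, p_edge):
    """Erdos-Renyi network over string node ids (isolated nodes kept)."""
    net = InteractionNetwork()
    names = [f"n{i:02d}" for i in range(n_nodes)]
    for name in names:
        net.add_node(name)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                net.add_edge(names[i], names[j], "rand")
    return net


def adjacency(net):
    adj = {n: set() for n in net.nodes}
    for a, b in net.edges:
        adj[a].add(b)
        adj[b].add(a)
    return adj
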