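import random

import networkx as nx
import pytest

from steinersub import SteinerInstance, largest_connected_component
from steinersub.fixtures import ar_hdac9_graph


@pytest.fixture
def fig2():
    return ar_hdac9_graph()


@pytest.fixture
def fig2_instance(fig2):
    return SteinerInstance(fig2, {"AR", "HDAC9"})


def random_instances(n_instances, seed, max_nodes=12, max_terminals=5):
    """Small random connected instances for oracle cross-checks."""
    rng = random.Random(seed)
    produced = 0
    attempt = 0
    while produced < n_instances:
        attempt += 1
        n = rng.randint(5, max_nodes)
        m = rng.randint(n - 1, min(n * (n - 1) // 2, n + 8))
        g = nx.gnm_random_graph(n, m, seed=seed * 10_000 + attempt)
        g = nx.relabel_nodes(g, {k: f"n{k:02d}" for k in g})
        g = largest_connected_component(g)
        if g.number_of_nodes() < 4:
            continue
        k = rng.randint(2, min(max_terminals, g.number_of_nodes()))
        terminals = rng.sample(sorted(g.nodes()), k)
        produced += 1
        yield SteinerInstance(g, terminals)
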