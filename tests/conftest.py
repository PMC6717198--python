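import numpy as np
import pytest

from hypermux import LayerGraph, MultiplexNetwork


@pytest.fixture
def triangle():
    """K3 on nodes 0,1,2."""
    return LayerGraph.from_edges([(0, 1), (0, 2), (1, 2)])


@pytest.fixture
def path3():
    """Path 0-1-2 on three nodes."""
    return LayerGraph.from_edges([(0, 1), (1, 2)])


def random_multiplex(rng: np.random.Generator) -> MultiplexNetwork:
    """A small random multiplex: 2-15 nodes, 1-3 layers, random edges,
    possibly isolated nodes and empty layers."""
    n = int(rng.integers(2, 16))
    n_layers = int(rng.integers(1, 4))
    # original labels: random strictly increasing ints (exercises the id map)
    labels = tuple(sorted(rng.choice(1000, size=n, replace=False).tolist()))
    universe = tuple(range(n))
    layers = []
    for _ in range(n_layers):
        p = rng.uniform(0.0, 0.6)
        edges = {(i, j) for i in range(n) for j in range(i + 1, n)
                 if rng.random() < p}
        layers.append(LayerGraph(nodes=universe, edges=frozenset(edges)))
    return MultiplexNetwork(layers=tuple(layers), node_labels=labels)
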