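import numpy as np
import pytest

from promote import BipartiteGraph, ProbabilisticNetwork
from promote.synth import GeneratorConfig, generate


@pytest.fixture
def worked_bipartite():
    """The reconstructed worked bipartite instance.

    Variables x1, x2, x3, x5, x6 against edge polynomials Z1 = {x1},
    Z2 = {x1, x2, x3}, Z4 = {x1, x2, x3, x5}, Z8 = {x6}; degrees
    x1:3, x2:2, x3:2, x5:1, x6:1.
    """
    links = {1: [1], 2: [1, 2, 3], 4: [1, 2, 3, 5], 8: [6]}
    probs = {1: 0.5, 2: 0.5, 4: 0.5, 8: 0.5}
    return BipartiteGraph.build(
        v1=[1, 2, 3, 5, 6], v2=[1, 2, 4, 8], links=links, edge_probs=probs
    )


def random_bipartite(rng, max_v1=6, max_v2=8):
    """A random bipartite instance with every variable in at least one polynomial."""
    nv1 = int(rng.integers(1, max_v1 + 1))
    nv2 = int(rng.integers(1, max_v2 + 1))
    links = {}
    for j in range(nv2):
        k = int(rng.integers(0, nv1 + 1))
        links[j] = list(rng.choice(nv1, size=min(k, nv1), replace=False))
    for i in range(nv1):
        if not any(i in members for members in links.values()):
            links[int(rng.integers(0, nv2))].append(i)
    probs = {j: float(rng.uniform(0.05, 0.95)) for j in range(nv2)}
    return BipartiteGraph.build(
        v1=range(nv1), v2=range(nv2), links=links, edge_probs=probs
    )


def random_small_network(rng, n_nodes=9, avg_degree=2.2, max_edges=10):
    """A random probabilistic network small enough for exhaustive oracles."""
    for attempt in range(100):
        seed = int(rng.integers(2**31))
        net = generate(
            GeneratorConfig(
                model="ER", n_nodes=n_nodes, avg_degree=avg_degree, seed=seed
            )
        )
        if 3 <= net.n_edges <= max_edges:
            return net
    raise RuntimeError("could not draw a small network")


@pytest.fixture
def two_triangles():
    """Two edge- and node-disjoint triangles with p = 0.5 on every edge."""
    edges = [
        ("a", "b", 0.5), ("b", "c", 0.5), ("c", "a", 0.5),
        ("x", "y", 0.5), ("y", "z", 0.5), ("z", "x", 0.5),
    ]
    return ProbabilisticNetwork.from_edges(edges)
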