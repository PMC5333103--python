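"""Shared fixtures: tiny hand-built networks and seeded synthetic ones."""

import numpy as np
import pytest

from netprio import (GeneNetwork, DiseaseGeneSet, SyntheticScenario,
                     generate_scenario, hub_fixture,
                     all_pairs_raw_distance, adjust_distance)


# Confidence scores whose edge distance 1000/S is exactly representable
# in binary floating point (quotient is m / 2^k); path sums over these
# are exact, so shortest-path implementations must agree bitwise.
EXACT_SCORES = np.array([1000, 800, 640, 500, 400, 320, 250, 200,
                         160, 125, 100, 80, 50, 40, 25, 20])


def floyd_warshall_reference(net):
    """Independent min-plus brute force over 1000/S edge distances."""
    genes = net.genes
    n = len(genes)
    idx = {g: i for i, g in enumerate(genes)}
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for (a, b), s in net.edges.items():
        w = 1000.0 / s
        i, j = idx[a], idx[b]
        d[i, j] = min(d[i, j], w)
        d[j, i] = d[i, j]
    for k in range(n):
        d = np.minimum(d, d[:, [k]] + d[[k], :])
    return genes, d


def random_connected_network(rng, n_min=5, n_max=50, extra_edge_p=0.15,
                             scores=None):
    """Random connected graph: spanning tree + extra Bernoulli edges."""
    n = int(rng.integers(n_min, n_max + 1))
    genes = [f"g{i:03d}" for i in range(n)]
    net = GeneNetwork(genes=genes)
    if scores is None:
        def draw():
            return int(rng.integers(1, 1001))
    else:
        def draw():
            return int(scores[rng.integers(len(scores))])
    for i in range(1, n):
        j = int(rng.integers(0, i))
        net.add_edge(genes[i], genes[j], draw())
    iu, ju = np.triu_indices(n, k=1)
    extra = rng.random(iu.size) < extra_edge_p
    for i, j in zip(iu[extra], ju[extra]):
        key = tuple(sorted((genes[i], genes[j])))
        if key not in net.edges:
            net.add_edge(genes[i], genes[j], draw())
    return net


@pytest.fixture
def path_network():
    """g1 -500- g2 -500- g3: a 3-gene path."""
    return GeneNetwork(edges=[("g1", "g2", 500), ("g2", "g3", 500)])


@pytest.fixture
def triangle_network():
    """Two strong hops beat one weak direct edge between g1 and g3."""
    return GeneNetwork(edges=[("g1", "g2", 1000), ("g2", "g3", 1000),
                              ("g1", "g3", 200)])


@pytest.fixture(scope="session")
def planted():
    """Standard planted-module scenario with distances precomputed."""
    net, sets = generate_scenario(SyntheticScenario(seed=11))
    dm = all_pairs_raw_distance(net)
    adm = adjust_distance(dm)
    return net, sets[0], dm, adm


@pytest.fixture(scope="session")
def hub_world():
    """Default hub-and-module fixture with distances precomputed."""
    net, ds, hub = hub_fixture()
    dm = all_pairs_raw_distance(net)
    adm = adjust_distance(dm)
    return net, ds, hub, dm, adm


@pytest.fixture
def small_disease(planted):
    _, ds, _, _ = planted
    return ds
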