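"""Shared fixtures: small deterministic networks and data bundles."""

import numpy as np
import pytest

import deeprw as d


def random_network(n_nodes: int, seed: int, extra_edge_prob: float = 0.15):
    """Random connected weighted network: a random spanning tree plus
    Bernoulli extra edges, weights uniform on (0, 1]."""
    rng = np.random.default_rng(seed)
    ids = [f"N{i:03d}" for i in range(n_nodes)]
    edges = []
    for i in range(1, n_nodes):
        j = int(rng.integers(0, i))
        edges.append((ids[i], ids[j], float(1.0 - rng.random())))
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < extra_edge_prob:
                edges.append((ids[i], ids[j], float(1.0 - rng.random())))
    try:
        return d.build_network(edges)
    except ValueError:  # duplicate of a tree edge with a new weight
        dedup = {}
        for a, b, w in edges:
            dedup.setdefault((min(a, b), max(a, b)), w)
        return d.build_network([(a, b, w) for (a, b), w in dedup.items()])


@pytest.fixture
def path_net():
    """Path A-B (weight 1), B-C (weight 2)."""
    return d.build_network([("A", "B", 1.0), ("B", "C", 2.0)])


@pytest.fixture
def two_node_net():
    return d.build_network([("A", "B", 1.0)])


@pytest.fixture
def two_clique_net():
    """Two dense 10-node cliques joined by a single weak bridge."""
    edges = []
    for block, prefix in ((0, "A"), (1, "B")):
        ids = [f"{prefix}{i:02d}" for i in range(10)]
        for i in range(10):
            for j in range(i + 1, 10):
                edges.append((ids[i], ids[j], 1.0))
    edges.append(("A00", "B00", 0.05))
    return d.build_network(edges)


@pytest.fixture(scope="session")
def small_bundle():
    """Strong-signal planted-partition bundle at desk scale (30+30)."""
    cfg = d.SimulationConfig(
        n_pos=30, n_neg=30, p_in=0.25, p_out=0.04,
        feature_effect=1.5, noise_sd=1.0, n_features=12, seed=20,
    )
    net, labels = d.simulate_network(cfg)
    feats = d.simulate_features(labels, cfg)
    return d.DataBundle(net=net, features=feats, labels=labels)


@pytest.fixture(scope="session")
def fast_training():
    """Short training schedule for CV-heavy tests."""
    return d.TrainingConfig(max_epochs=60, patience_epochs=10, seed=0)
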