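"""Synthetic gene networks, features and labels for end-to-end testing.

Emulates the statistical structure the method assumes in real data:
disease genes are better connected to each other than to the rest of
the network (guilt by association), and node features carry a
label-correlated signal (as tissue-expression profiles do). The
network is a planted-partition graph — an edge joins a same-class pair
with probability ``p_in`` and a cross-class pair with probability
``p_out`` — with edge weights drawn uniformly from (0, 1] in the style
of probabilistic functional-association scores. Features are Gaussian
with a per-feature signed mean shift of size ``feature_effect`` for
the positive class.

Network signal (``p_in`` vs ``p_out``) and feature signal
(``feature_effect``) are independent dials, so the walk-embedding
branch and the feature-propagation branch of the model can be stressed
separately. The default configuration mirrors the 142 + 142 gene
design of the motivating study at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .evaluation import DataBundle
from .gcn import NodeFeatureMatrix
from .graph import GeneNetwork, build_network, read_edge_list, write_edge_list

__all__ = [
    "SimulationConfig",
    "simulate_network",
    "simulate_features",
    "write_fixture",
    "read_fixture",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; defaults are the strong-signal study conditions."""

    n_pos: int = 142
    n_neg: int = 142
    p_in: float = 0.10
    p_out: float = 0.02
    weight_dist: str = "uniform"
    n_features: int = 30
    feature_effect: float = 1.5
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_in <= 1.0 and 0.0 <= self.p_out <= 1.0):
            raise ValueError("edge probabilities must be in [0, 1]")
        if self.n_pos < 10 or self.n_neg < 10:
            raise ValueError("need at least 10 genes per class")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.weight_dist != "uniform":
            raise ValueError(f"unknown weight_dist {self.weight_dist!r}")


def _draw_weights(rng: np.random.Generator, size: int) -> np.ndarray:
    # uniform on (0, 1]: HumanNet-style positive association scores
    return 1.0 - rng.random(size)


def simulate_network(
    cfg: SimulationConfig, rewire_isolated: bool = True
) -> tuple[GeneNetwork, dict[str, int]]:
    """Planted-partition network plus gene labels.

    Nodes left isolated by the Bernoulli draw are re-wired to one
    random same-class partner so the no-isolated-node invariant holds;
    with ``rewire_isolated=False`` they are simply pruned (and dropped
    from the returned labels).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_pos + cfg.n_neg
    ids = [f"G{i + 1:04d}" for i in range(n)]
    z = np.zeros(n, dtype=int)
    z[rng.permutation(n)[: cfg.n_pos]] = 1

    iu, ju = np.triu_indices(n, k=1)
    same = z[iu] == z[ju]
    prob = np.where(same, cfg.p_in, cfg.p_out)
    keep = rng.random(len(iu)) < prob
    ei, ej = iu[keep], ju[keep]
    w = _draw_weights(rng, len(ei))
    edges = [(ids[a], ids[b], float(wk)) for a, b, wk in zip(ei, ej, w)]

    if rewire_isolated:
        connected = np.zeros(n, dtype=bool)
        connected[ei] = True
        connected[ej] = True
        for node in np.flatnonzero(~connected):
            if connected[node]:  # picked up by an earlier re-wiring
                continue
            mates = np.flatnonzero((z == z[node]) & (np.arange(n) != node))
            mate = int(rng.choice(mates))
            edges.append((ids[node], ids[mate], float(_draw_weights(rng, 1)[0])))
            connected[node] = connected[mate] = True

    net = build_network(edges)
    labels = {g: int(z[i]) for i, g in enumerate(ids) if g in set(net.node_ids)}
    return net, labels


def simulate_features(labels: dict[str, int], cfg: SimulationConfig) -> NodeFeatureMatrix:
    """Label-correlated Gaussian features.

    Feature j of gene i is Normal(effect * z_i * s_j, noise_sd^2) with
    z_i the label and s_j a fixed random sign per feature; effect 0
    gives pure label-independent noise.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    nodes = tuple(sorted(labels))
    z = np.array([labels[g] for g in nodes], dtype=np.float64)
    signs = rng.choice([-1.0, 1.0], size=cfg.n_features)
    mean = cfg.feature_effect * z[:, None] * signs[None, :]
    feats = mean + rng.normal(0.0, cfg.noise_sd, size=(len(nodes), cfg.n_features))
    return NodeFeatureMatrix(node_ids=nodes, features=feats)


def write_fixture(
    directory,
    net: GeneNetwork,
    labels: dict[str, int],
    features: NodeFeatureMatrix,
) -> None:
    """Write edges.tsv, positives.txt, negatives.txt and features.tsv.

    The files round-trip losslessly through the package readers and
    parse under the HumanNet-style edge-list reader; output bytes are
    deterministic for fixed inputs.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_edge_list(d / "edges.tsv", net)
    with open(d / "positives.txt", "wt", encoding="utf-8") as fh:
        for g in sorted(g for g, y in labels.items() if y == 1):
            fh.write(g + "\n")
    with open(d / "negatives.txt", "wt", encoding="utf-8") as fh:
        for g in sorted(g for g, y in labels.items() if y == 0):
            fh.write(g + "\n")
    with open(d / "features.tsv", "wt", encoding="utf-8") as fh:
        fh.write(
            "#gene\t" + "\t".join(f"f{j}" for j in range(features.features.shape[1])) + "\n"
        )
        for g, row in zip(features.node_ids, features.features):
            fh.write(g + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_gene_list(path) -> list[str]:
    with open(path, "rt", encoding="utf-8") as fh:
        return [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]


def read_feature_table(path) -> NodeFeatureMatrix:
    nodes: list[str] = []
    rows: list[list[float]] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            nodes.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    order = np.argsort(nodes)
    return NodeFeatureMatrix(
        node_ids=tuple(nodes[i] for i in order),
        features=np.asarray(rows, dtype=np.float64)[order],
    )


def read_fixture(directory) -> DataBundle:
    """Load a fixture directory back into a cross-validation bundle."""
    d = Path(directory)
    net = build_network(read_edge_list(d / "edges.tsv"))
    labels = {g: 1 for g in read_gene_list(d / "positives.txt")}
    labels.update({g: 0 for g in read_gene_list(d / "negatives.txt")})
    features = read_feature_table(d / "features.tsv")
    if features.node_ids != net.node_ids:
        raise ValueError("feature table genes do not match the network")
    return DataBundle(net=net, features=features, labels=labels)
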