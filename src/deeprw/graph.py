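"""Weighted gene-interaction network.

Builds an undirected, weighted graph over gene identifiers from an edge
list (HumanNet-style functional associations: each link carries a
probability-like weight) and exposes the matrix views every downstream
stage consumes: the weighted adjacency ``W``, the graph Laplacian
``L = D - W``, the self-loop-augmented adjacency ``A' = W + I`` and its
symmetric normalization ``D'^{-1/2} A' D'^{-1/2}``.

Genes that end up with no positive-weight interaction are removed at
build time: a node the network says nothing about cannot be embedded by
walking or by neighborhood aggregation, so keeping it would only
produce undefined scores downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeneNetwork",
    "NormalizedAdjacency",
    "build_network",
    "laplacian",
    "augment_adjacency",
    "normalize_adjacency",
    "read_edge_list",
    "write_edge_list",
]


@dataclass(frozen=True)
class GeneNetwork:
    """Undirected weighted graph with a dense symmetric adjacency view.

    Node order is the lexicographic sort of the gene identifiers, fixed
    at build time; every matrix and embedding produced from this network
    uses that order.
    """

    node_ids: tuple[str, ...]
    adjacency: np.ndarray  # (n, n) float64, symmetric, zero diagonal
    edge_count: int
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_index", {g: i for i, g in enumerate(self.node_ids)}
        )

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def index_of(self, node: str) -> int:
        try:
            return self._index[node]
        except KeyError:
            raise KeyError(f"unknown node {node!r}") from None

    def degrees(self) -> np.ndarray:
        """Weighted degree (row sums of the adjacency)."""
        return self.adjacency.sum(axis=1)

    def neighbors(self, node: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (neighbor indices, edge weights) of ``node``."""
        row = self.adjacency[self.index_of(node)]
        idx = np.flatnonzero(row > 0)
        return idx, row[idx]


@dataclass(frozen=True)
class NormalizedAdjacency:
    """Symmetrically normalized augmented adjacency D'^{-1/2} A' D'^{-1/2}."""

    matrix: np.ndarray
    source: GeneNetwork


def build_network(
    edges: list[tuple[str, str, float]],
) -> GeneNetwork:
    """Assemble a :class:`GeneNetwork` from (gene_a, gene_b, weight) records.

    Reciprocal and duplicate records with equal weight collapse to one
    undirected edge; the same pair listed with two different weights is
    an error (fail loud on dirty input rather than silently averaging).
    Zero-weight records are dropped, and any gene left without a
    positive-weight edge is pruned.
    """
    if not edges:
        raise ValueError("empty network")

    weights: dict[tuple[str, str], float] = {}
    for a, b, w in edges:
        if not isinstance(a, str) or not isinstance(b, str) or not a or not b:
            raise ValueError(f"gene identifiers must be non-empty strings: ({a!r}, {b!r})")
        w = float(w)
        if not math.isfinite(w) or w < 0:
            raise ValueError(f"edge weight must be finite and >= 0: {a}-{b} = {w}")
        if a == b:
            raise ValueError(f"self-edge in input: {a}")
        key = (a, b) if a < b else (b, a)
        if key in weights:
            if not math.isclose(weights[key], w, rel_tol=1e-12, abs_tol=0.0):
                raise ValueError(
                    f"conflicting edge weight for {key[0]}-{key[1]}: "
                    f"{weights[key]} vs {w}"
                )
        else:
            weights[key] = w

    # drop zero-weight records, then prune genes with no remaining edge
    weights = {k: w for k, w in weights.items() if w > 0}
    if not weights:
        raise ValueError("empty network")

    nodes = sorted({g for pair in weights for g in pair})
    index = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    adj = np.zeros((n, n), dtype=np.float64)
    for (a, b), w in weights.items():
        i, j = index[a], index[b]
        adj[i, j] = adj[j, i] = w

    return GeneNetwork(node_ids=tuple(nodes), adjacency=adj, edge_count=len(weights))


def laplacian(net: GeneNetwork) -> np.ndarray:
    """Graph Laplacian L = D - W, D the diagonal weighted-degree matrix.

    Row sums of L are zero by construction. The Laplacian is not
    consumed by the convolutional encoder (which propagates through the
    normalized augmented adjacency instead); it is provided as the
    standard spectral view of the network.
    """
    return np.diag(net.degrees()) - net.adjacency


def augment_adjacency(net: GeneNetwork) -> np.ndarray:
    """A' = W + I: add unit self-loops so each node retains its own signal.

    The self-loop weight is exactly 1 regardless of the edge-weight
    scale.
    """
    return net.adjacency + np.eye(net.n_nodes)


def normalize_adjacency(net: GeneNetwork) -> NormalizedAdjacency:
    """Symmetric normalization D'^{-1/2} (W + I) D'^{-1/2}.

    D' is the diagonal matrix of row sums of the augmented adjacency.
    The result is symmetric, nonnegative, and has spectral radius at
    most 1, which is what keeps repeated propagation from blowing up.
    """
    a_prime = augment_adjacency(net)
    d_prime = a_prime.sum(axis=1)
    if np.any(d_prime <= 0):
        raise ValueError("zero row sum in augmented adjacency")
    inv_sqrt = 1.0 / np.sqrt(d_prime)
    # outer product is exactly symmetric, so the result is too
    mat = a_prime * np.outer(inv_sqrt, inv_sqrt)
    return NormalizedAdjacency(matrix=mat, source=net)


def read_edge_list(path) -> list[tuple[str, str, float]]:
    """Read a tab-separated edge list: gene_a, gene_b, weight.

    Lines starting with ``#`` are comments/headers. HumanNet flat files
    parse under this reader.
    """
    edges: list[tuple[str, str, float]] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, got {len(parts)}"
                )
            edges.append((parts[0], parts[1], float(parts[2])))
    return edges


def write_edge_list(path, net: GeneNetwork) -> None:
    """Write one row per undirected edge, genes sorted within each row."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("#gene_a\tgene_b\tweight\n")
        n = net.n_nodes
        for i in range(n):
            for j in range(i + 1, n):
                w = net.adjacency[i, j]
                if w > 0:
                    fh.write(f"{net.node_ids[i]}\t{net.node_ids[j]}\t{float(w)!r}\n")
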