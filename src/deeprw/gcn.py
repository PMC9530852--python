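"""Graph convolutional encoder.

The second network-representation branch: node features (e.g. tissue
expression) are propagated through the symmetrically normalized,
self-loop-augmented adjacency. One layer computes

    H' = LeakyReLU( D'^{-1/2} A' D'^{-1/2} H W ),

so each node's new representation mixes its own signal with its
neighborhood's, weighted by edge strength. The default encoder stacks
three such layers; the depth is exposed because stacking many layers
over-smooths — repeated averaging drives all node representations
toward a common value and the classes become indistinguishable.

The forward pass here is deterministic given the weights; the weights
themselves are trained end-to-end with the downstream classifier (see
:mod:`deeprw.classifier`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .embeddings import EmbeddingMatrix
from .graph import NormalizedAdjacency

__all__ = [
    "NodeFeatureMatrix",
    "GCNParams",
    "leaky_relu",
    "gcn_layer",
    "gcn_forward",
    "init_gcn_params",
]

NEGATIVE_SLOPE = 0.2


@dataclass(frozen=True)
class NodeFeatureMatrix:
    """Per-node feature vectors, rows in network node order."""

    node_ids: tuple[str, ...]
    features: np.ndarray  # (n_nodes, n_features)

    def __post_init__(self) -> None:
        if self.features.ndim != 2 or self.features.shape[0] != len(self.node_ids):
            raise ValueError("feature matrix rows must match node ids")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain non-finite values")


@dataclass
class GCNParams:
    """Per-layer weight matrices of the convolutional encoder."""

    layer_weights: list[np.ndarray]
    negative_slope: float = NEGATIVE_SLOPE
    _check: None = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        if not self.layer_weights:
            raise ValueError("at least one layer required")
        for wa, wb in zip(self.layer_weights, self.layer_weights[1:]):
            if wa.shape[1] != wb.shape[0]:
                raise ValueError(
                    f"incompatible consecutive layer shapes {wa.shape} -> {wb.shape}"
                )

    @property
    def n_layers(self) -> int:
        return len(self.layer_weights)


def leaky_relu(x, negative_slope: float = NEGATIVE_SLOPE):
    """LeakyReLU(x) = max(0, x) + negative_slope * min(0, x), slope 0.2."""
    x = np.asarray(x, dtype=np.float64)
    out = np.maximum(0.0, x) + negative_slope * np.minimum(0.0, x)
    return out if out.ndim else float(out)


def _as_matrix(a_hat: NormalizedAdjacency | np.ndarray) -> np.ndarray:
    return a_hat.matrix if isinstance(a_hat, NormalizedAdjacency) else np.asarray(a_hat)


def gcn_layer(
    x: np.ndarray,
    a_hat: NormalizedAdjacency | np.ndarray,
    w_l: np.ndarray,
    negative_slope: float = NEGATIVE_SLOPE,
) -> np.ndarray:
    """One propagation step: LeakyReLU(A_hat @ X @ W_l)."""
    a = _as_matrix(a_hat)
    x = np.asarray(x, dtype=np.float64)
    if a.shape[1] != x.shape[0]:
        raise ValueError(f"adjacency {a.shape} incompatible with features {x.shape}")
    if x.shape[1] != w_l.shape[0]:
        raise ValueError(f"features {x.shape} incompatible with weights {w_l.shape}")
    return leaky_relu(a @ x @ w_l, negative_slope)


def gcn_forward(
    x: NodeFeatureMatrix | np.ndarray,
    a_hat: NormalizedAdjacency | np.ndarray,
    params: GCNParams,
) -> EmbeddingMatrix | np.ndarray:
    """Compose ``params.n_layers`` propagation steps.

    With a :class:`NodeFeatureMatrix` input the result is an
    :class:`EmbeddingMatrix` in the same node order; a bare array input
    returns a bare array.
    """
    if isinstance(x, NodeFeatureMatrix):
        h = gcn_forward(x.features, a_hat, params)
        return EmbeddingMatrix(node_ids=x.node_ids, vectors=h)
    h = np.asarray(x, dtype=np.float64)
    for w in params.layer_weights:
        h = gcn_layer(h, a_hat, w, params.negative_slope)
    return h


def init_gcn_params(
    n_features: int,
    hidden_dim: int,
    n_layers: int,
    seed: int,
    negative_slope: float = NEGATIVE_SLOPE,
) -> GCNParams:
    """Glorot-uniform initialization of an encoder with uniform hidden width."""
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    rng = np.random.default_rng(seed)
    dims = [n_features] + [hidden_dim] * n_layers
    weights = []
    for d_in, d_out in zip(dims, dims[1:]):
        limit = np.sqrt(6.0 / (d_in + d_out))
        weights.append(rng.uniform(-limit, limit, size=(d_in, d_out)))
    return GCNParams(layer_weights=weights, negative_slope=negative_slope)
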