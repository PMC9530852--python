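"""Weighted random walks and skip-gram vertex embeddings.

The first of the two network-representation branches: truncated random
walks over the weighted gene network are treated as sentences, and a
skip-gram model is trained on them so that genes sharing walk context
(i.e. well-connected neighborhoods) end up with nearby vectors.

Walks are first-order: from vertex ``v`` the next vertex is drawn from
the neighbors of ``v`` with probability proportional to the incident
edge weight. The training objective for a center vertex is the negative
log-likelihood of the vertices inside a sliding window around it,

    L(v_i) = - sum_j log P(v_{c_j} | v_i),

with P a softmax over vector inner products. ``skipgram_loss`` computes
this reference objective exactly (full softmax); ``train_skipgram``
optimizes it with the standard negative-sampling estimator for speed.
Training is single-threaded and fully seeded, so identical inputs give
bit-identical embeddings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numba
import numpy as np
from scipy.special import logsumexp

from .embeddings import EmbeddingMatrix
from .graph import GeneNetwork

__all__ = [
    "WalkCorpus",
    "SkipGramModel",
    "transition_distribution",
    "generate_walks",
    "skipgram_loss",
    "train_skipgram",
]


@dataclass(frozen=True)
class WalkCorpus:
    """Node-identifier sequences produced by weighted random walks."""

    walks: tuple[tuple[str, ...], ...]
    walk_length: int
    walks_per_node: int
    seed: int


@dataclass(frozen=True)
class SkipGramModel:
    """Skip-gram vertex model: window size, iteration count and the vectors."""

    embedding_dim: int
    window: int
    iterations: int
    node_vectors: EmbeddingMatrix


def transition_distribution(net: GeneNetwork, v: str) -> dict[str, float]:
    """One-step walk distribution from ``v``: neighbors weighted by edge weight."""
    idx, w = net.neighbors(v)  # raises KeyError on unknown node
    p = w / w.sum()
    return {net.node_ids[i]: float(pi) for i, pi in zip(idx, p)}


def generate_walks(
    net: GeneNetwork, walks_per_node: int, walk_length: int, seed: int
) -> WalkCorpus:
    """Sample ``walks_per_node`` weighted random walks starting at every node.

    Each step moves to a neighbor with probability proportional to the
    edge weight. Deterministic for a fixed seed.
    """
    if walk_length < 2:
        raise ValueError("walk_length must be >= 2")
    if walks_per_node < 1:
        raise ValueError("walks_per_node must be >= 1")

    rng = np.random.default_rng(seed)
    n = net.n_nodes
    # per-node neighbor index arrays and cumulative transition weights
    nbr_idx: list[np.ndarray] = []
    nbr_cum: list[np.ndarray] = []
    for i in range(n):
        row = net.adjacency[i]
        idx = np.flatnonzero(row > 0)
        cum = np.cumsum(row[idx])
        nbr_idx.append(idx)
        nbr_cum.append(cum / cum[-1])

    walks: list[tuple[str, ...]] = []
    ids = net.node_ids
    for start in range(n):
        for _ in range(walks_per_node):
            walk = [start]
            cur = start
            for _ in range(walk_length - 1):
                u = rng.random()
                cur = int(nbr_idx[cur][np.searchsorted(nbr_cum[cur], u)])
                walk.append(cur)
            walks.append(tuple(ids[i] for i in walk))
    return WalkCorpus(
        walks=tuple(walks),
        walk_length=walk_length,
        walks_per_node=walks_per_node,
        seed=seed,
    )


def skipgram_loss(model: SkipGramModel, walk, center_index: int) -> float:
    """Exact full-softmax skip-gram loss at one walk position.

    Sums -log P(context | center) over the at most 2*window context
    vertices around ``center_index``; P is the softmax over inner
    products of the node vectors. This is the reference objective that
    negative-sampling training approximates.
    """
    walk = list(walk)
    if not 0 <= center_index < len(walk):
        raise IndexError("center_index outside walk")
    if model.window < 1:
        raise ValueError("window must be >= 1")
    emb = model.node_vectors
    index = {g: i for i, g in enumerate(emb.node_ids)}
    w = model.window
    ctx = walk[max(0, center_index - w): center_index]
    ctx += walk[center_index + 1: center_index + 1 + w]
    vi = emb.vectors[index[walk[center_index]]]
    logits = emb.vectors @ vi
    logp = logits - logsumexp(logits)
    return float(-sum(logp[index[c]] for c in ctx))


def _init_vectors(n_nodes: int, dim: int, seed: int) -> np.ndarray:
    """word2vec-style initialization: uniform in (-0.5/d, 0.5/d)."""
    rng = np.random.default_rng(seed)
    return ((rng.random((n_nodes, dim)) - 0.5) / dim).astype(np.float64)


def _corpus_pairs(
    walks_idx: np.ndarray, window: int
) -> tuple[np.ndarray, np.ndarray]:
    """All (center, context) index pairs with |offset| <= window."""
    centers: list[np.ndarray] = []
    contexts: list[np.ndarray] = []
    length = walks_idx.shape[1]
    for off in range(1, min(window, length - 1) + 1):
        left = walks_idx[:, :-off].ravel()
        right = walks_idx[:, off:].ravel()
        centers.append(left)
        contexts.append(right)
        centers.append(right)
        contexts.append(left)
    return (
        np.concatenate(centers).astype(np.int64),
        np.concatenate(contexts).astype(np.int64),
    )


@numba.njit(cache=True, fastmath=True)
def _sgd_pass(
    w_in: np.ndarray,
    w_out: np.ndarray,
    centers: np.ndarray,
    contexts: np.ndarray,
    order: np.ndarray,
    negatives: np.ndarray,  # (n_pairs, k) noise draws for this pass
    lr_start: float,
    lr_end: float,
) -> None:
    """One SGD pass over all (center, context) pairs, word2vec style.

    Per positive pair: one sigmoid update toward the context vector and
    ``k`` updates away from noise vectors; the learning rate decays
    linearly from ``lr_start`` to ``lr_end`` across the pass. Updates
    are applied pair by pair (no batching), single-threaded.
    """
    n_pairs = order.shape[0]
    dim = w_in.shape[1]
    k = negatives.shape[1]
    buf = np.empty(dim)
    for t in range(n_pairs):
        p = order[t]
        c = centers[p]
        o = contexts[p]
        lr = lr_start + (lr_end - lr_start) * (t / n_pairs)
        for j in range(dim):
            buf[j] = 0.0
        for s in range(k + 1):
            target = o if s == 0 else negatives[p, s - 1]
            label = 1.0 if s == 0 else 0.0
            dot = 0.0
            for j in range(dim):
                dot += w_in[c, j] * w_out[target, j]
            g = (label - 1.0 / (1.0 + np.exp(-dot))) * lr
            for j in range(dim):
                buf[j] += g * w_out[target, j]
                w_out[target, j] += g * w_in[c, j]
        for j in range(dim):
            w_in[c, j] += buf[j]


def train_skipgram(
    corpus: WalkCorpus,
    dim: int,
    window: int = 10,
    iterations: int = 10,
    seed: int = 0,
    node_ids: tuple[str, ...] | None = None,
    negative: int = 5,
    learning_rate: float = 0.025,
) -> EmbeddingMatrix:
    """Train skip-gram vertex embeddings on a walk corpus.

    Uses negative sampling (``negative`` noise draws per positive pair,
    unigram^0.75 noise distribution) with stochastic gradient descent
    and a linearly decaying learning rate, single-threaded so a fixed
    seed reproduces the matrix exactly. ``iterations`` full passes over
    the (center, context) pairs; 0 returns the initialization
    unchanged.

    If ``node_ids`` is given (the network's node order), every listed
    node must occur in the corpus and the output rows follow that order;
    otherwise the sorted set of corpus nodes is used.
    """
    if not corpus.walks:
        raise ValueError("empty walk corpus")
    seen = {g for walk in corpus.walks for g in walk}
    if node_ids is None:
        node_ids = tuple(sorted(seen))
    else:
        missing = sorted(set(node_ids) - seen)
        if missing:
            raise ValueError(f"nodes missing from corpus: {missing}")
    index = {g: i for i, g in enumerate(node_ids)}
    n = len(node_ids)

    walks_idx = np.asarray(
        [[index[g] for g in walk] for walk in corpus.walks], dtype=np.int64
    )
    centers, contexts = _corpus_pairs(walks_idx, window)
    n_pairs = centers.shape[0]

    w_in = _init_vectors(n, dim, seed)
    if iterations == 0:
        return EmbeddingMatrix(node_ids=node_ids, vectors=w_in)
    w_out = np.zeros((n, dim), dtype=np.float64)

    # unigram^0.75 noise distribution over corpus frequencies
    freq = np.bincount(walks_idx.ravel(), minlength=n).astype(np.float64)
    noise = freq**0.75
    noise_cum = np.cumsum(noise / noise.sum())

    rng = np.random.default_rng(seed)
    min_lr = 1e-4
    for it in range(iterations):
        order = rng.permutation(n_pairs)
        negatives = np.searchsorted(noise_cum, rng.random((n_pairs, negative)))
        frac0 = it / iterations
        frac1 = (it + 1) / iterations
        lr0 = max(learning_rate * (1.0 - frac0), min_lr)
        lr1 = max(learning_rate * (1.0 - frac1), min_lr)
        _sgd_pass(w_in, w_out, centers, contexts, order, negatives, lr0, lr1)

    return EmbeddingMatrix(node_ids=node_ids, vectors=w_in)
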