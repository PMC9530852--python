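"""Per-node embedding container shared by the walk-based and convolutional encoders."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EmbeddingMatrix", "write_embedding_tsv", "read_embedding_tsv"]


@dataclass(frozen=True)
class EmbeddingMatrix:
    """One real-valued vector per node, rows in network node order."""

    node_ids: tuple[str, ...]
    vectors: np.ndarray  # (n_nodes, d)

    def __post_init__(self) -> None:
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.node_ids):
            raise ValueError(
                f"vectors shape {self.vectors.shape} does not match "
                f"{len(self.node_ids)} node ids"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("embedding contains non-finite values")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def row(self, node: str) -> np.ndarray:
        return self.vectors[self.node_ids.index(node)]


def write_embedding_tsv(path, emb: EmbeddingMatrix) -> None:
    """Write node id + d value columns, one row per node."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("#node\t" + "\t".join(f"d{k}" for k in range(emb.dim)) + "\n")
        for node, vec in zip(emb.node_ids, emb.vectors):
            fh.write(node + "\t" + "\t".join(repr(float(v)) for v in vec) + "\n")


def read_embedding_tsv(path) -> EmbeddingMatrix:
    nodes: list[str] = []
    rows: list[list[float]] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            nodes.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    return EmbeddingMatrix(node_ids=tuple(nodes), vectors=np.asarray(rows, dtype=np.float64))
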