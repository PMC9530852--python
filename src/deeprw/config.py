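"""Run configuration: every tunable hyperparameter in one validated record."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """Hyperparameters of the full pipeline with their published defaults.

    Walk/skip-gram: window 10, 10 training iterations; encoder: 3
    convolutional layers; evaluation: 10-fold cross-validation repeated
    10 times; training: Adam with default parameters and early
    stopping with 50-epoch patience.
    """

    # deep-walk branch
    window: int = 10
    skipgram_iterations: int = 10
    embedding_dim: int = 64
    walks_per_node: int = 10
    walk_length: int = 40
    # convolutional encoder
    gcn_layers: int = 3
    gcn_hidden: int = 64
    # prediction DNN
    dnn_hidden: tuple[int, ...] = (64, 32)
    max_epochs: int = 200
    patience_epochs: int = 50
    learning_rate: float = 1e-3
    batch_size: int | None = None
    validation_fraction: float = 0.1
    # evaluation
    k: int = 10
    repeats: int = 10
    restart_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        positive_ints = (
            "window", "skipgram_iterations", "embedding_dim", "walks_per_node",
            "gcn_layers", "gcn_hidden", "max_epochs", "k", "repeats",
        )
        for name in positive_ints:
            v = getattr(self, name)
            if not isinstance(v, int) or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.walk_length < 2:
            raise ValueError("walk_length must be >= 2")
        if self.patience_epochs < 0:
            raise ValueError("patience_epochs must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not 0.0 < self.restart_prob <= 1.0:
            raise ValueError("restart_prob must be in (0, 1]")
        if not 0.0 < self.validation_fraction <= 0.5:
            raise ValueError("validation_fraction must be in (0, 0.5]")
        if not all(isinstance(w, int) and w >= 1 for w in self.dnn_hidden):
            raise ValueError("dnn_hidden must be positive integers")
        if self.seed < 0:
            raise ValueError("seed must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Load from YAML; unknown keys are rejected, every field validated."""
        with open(path, "rt", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        if "dnn_hidden" in raw:
            raw["dnn_hidden"] = tuple(raw["dnn_hidden"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dnn_hidden"] = list(self.dnn_hidden)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
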