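"""Feature fusion and the feed-forward prediction module.

The two vertex representations — skip-gram walk embeddings and the
graph-convolutional encoding of node features — are fused by
concatenation and passed to a three-layer feed-forward network: two
hidden transforms (affine, batch normalization, LeakyReLU) and an
output transform followed by a two-class softmax. The loss is binary
cross-entropy on the predicted probability of the positive
(disease-associated) class,

    Loss = -y log(p) - (1 - y) log(1 - p).

Because the convolutional encoder carries no supervision of its own,
its weights are trained jointly with the classifier under this loss;
the walk embeddings are trained separately (unsupervised) and stay
frozen here. Training is full-graph and transductive — the encoder
propagates over every node while the loss is taken on labelled
training rows only — with Adam, a stratified held-out validation split,
and early stopping on validation loss.

All gradients are derived analytically and implemented directly in
NumPy (the architecture is small and fixed); a finite-difference check
in the test suite pins them down.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split

from .embeddings import EmbeddingMatrix
from .gcn import GCNParams, NodeFeatureMatrix, init_gcn_params, leaky_relu
from .graph import GeneNetwork, normalize_adjacency

__all__ = [
    "DNNParams",
    "TrainingConfig",
    "Prediction",
    "TrainedModel",
    "fuse",
    "dnn_forward",
    "bce_loss",
    "train_model",
    "predict",
    "score_nodes",
]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9
_CLIP_EPS = 1e-7


def fuse(dw: EmbeddingMatrix, gc: EmbeddingMatrix) -> EmbeddingMatrix:
    """Concatenate two per-node representations row-wise.

    Both inputs must list the same nodes in the same order; the fused
    dimension is the sum of the two.
    """
    if dw.node_ids != gc.node_ids:
        raise ValueError("node order mismatch between representations")
    return EmbeddingMatrix(
        node_ids=dw.node_ids,
        vectors=np.concatenate([dw.vectors, gc.vectors], axis=1),
    )


@dataclass
class DNNParams:
    """Weights, biases and batch-normalization state of the prediction DNN.

    ``layer_weights[l]`` has shape (d_in, d_out); hidden layers carry
    batch-norm scale/shift plus running mean/variance, the final layer
    maps to 2 logits.
    """

    layer_weights: list[np.ndarray]
    layer_biases: list[np.ndarray]
    bn_gamma: list[np.ndarray]
    bn_beta: list[np.ndarray]
    bn_mean: list[np.ndarray]
    bn_var: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.layer_weights) != len(self.layer_biases):
            raise ValueError("weights/biases length mismatch")
        n_hidden = len(self.layer_weights) - 1
        for lst in (self.bn_gamma, self.bn_beta, self.bn_mean, self.bn_var):
            if len(lst) != n_hidden:
                raise ValueError("batch-norm state must cover every hidden layer")
        if self.layer_weights[-1].shape[1] != 2:
            raise ValueError("final layer must output 2 logits")

    @property
    def n_layers(self) -> int:
        return len(self.layer_weights)


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization settings for the joint encoder + classifier fit.

    ``max_epochs``/``patience`` default to 200/50: train until the
    held-out validation loss has not improved for ``patience`` epochs.
    Setting ``max_epochs=50`` reproduces the strict fixed-budget
    schedule (50 epochs, patience never binding). ``batch_size=None``
    means full-batch updates.
    """

    max_epochs: int = 200
    patience_epochs: int = 50
    learning_rate: float = 1e-3
    batch_size: int | None = None
    seed: int = 0
    validation_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.patience_epochs < 0:
            raise ValueError("patience_epochs must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size is not None and self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (batch norm needs a batch)")
        if not 0.0 < self.validation_fraction <= 0.5:
            raise ValueError("validation_fraction must be in (0, 0.5]")


@dataclass(frozen=True)
class Prediction:
    node_id: str
    probability_positive: float
    label: int


def init_dnn_params(input_dim: int, hidden_widths: tuple[int, ...], seed: int) -> DNNParams:
    """Glorot-uniform weights, zero biases, identity batch-norm."""
    rng = np.random.default_rng(seed)
    dims = [input_dim, *hidden_widths, 2]
    weights, biases = [], []
    for d_in, d_out in zip(dims, dims[1:]):
        limit = np.sqrt(6.0 / (d_in + d_out))
        weights.append(rng.uniform(-limit, limit, size=(d_in, d_out)))
        biases.append(np.zeros(d_out))
    n_hidden = len(hidden_widths)
    return DNNParams(
        layer_weights=weights,
        layer_biases=biases,
        bn_gamma=[np.ones(w) for w in hidden_widths],
        bn_beta=[np.zeros(w) for w in hidden_widths],
        bn_mean=[np.zeros(w) for w in hidden_widths],
        bn_var=[np.ones(w) for w in hidden_widths],
    )


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _dnn_forward_cached(
    x: np.ndarray, params: DNNParams, training: bool, update_running: bool = False
):
    """Forward pass returning class probabilities and per-layer caches."""
    caches = []
    h = np.asarray(x, dtype=np.float64)
    n_hidden = params.n_layers - 1
    for l in range(n_hidden):
        z = h @ params.layer_weights[l] + params.layer_biases[l]
        if training:
            mu = z.mean(axis=0)
            var = z.var(axis=0)
            if update_running:
                params.bn_mean[l] = (
                    _BN_MOMENTUM * params.bn_mean[l] + (1 - _BN_MOMENTUM) * mu
                )
                params.bn_var[l] = (
                    _BN_MOMENTUM * params.bn_var[l] + (1 - _BN_MOMENTUM) * var
                )
        else:
            mu = params.bn_mean[l]
            var = params.bn_var[l]
        inv_std = 1.0 / np.sqrt(var + _BN_EPS)
        z_hat = (z - mu) * inv_std
        a = params.bn_gamma[l] * z_hat + params.bn_beta[l]
        out = leaky_relu(a)
        caches.append({"h_in": h, "z_hat": z_hat, "inv_std": inv_std, "a": a})
        h = out
    logits = h @ params.layer_weights[-1] + params.layer_biases[-1]
    probs = _softmax(logits)
    caches.append({"h_in": h})
    return probs, caches


def dnn_forward(
    fused: EmbeddingMatrix | np.ndarray, params: DNNParams, training_mode: bool = False
) -> np.ndarray:
    """Class-probability matrix (n x 2); rows sum to 1.

    ``training_mode`` selects batch statistics for normalization;
    inference mode uses the stored running statistics and is
    deterministic.
    """
    x = fused.vectors if isinstance(fused, EmbeddingMatrix) else np.asarray(fused)
    if x.shape[1] != params.layer_weights[0].shape[0]:
        raise ValueError(
            f"input dim {x.shape[1]} incompatible with first layer "
            f"{params.layer_weights[0].shape}"
        )
    probs, _ = _dnn_forward_cached(x, params, training=training_mode)
    return probs


def bce_loss(y, p) -> float:
    """Binary cross-entropy -y log p - (1-y) log(1-p); mean over a batch.

    Probabilities are clipped to [1e-7, 1 - 1e-7] so the loss stays
    finite at saturated predictions.
    """
    y = np.asarray(y, dtype=np.float64)
    p = np.clip(np.asarray(p, dtype=np.float64), _CLIP_EPS, 1 - _CLIP_EPS)
    return float(np.mean(-y * np.log(p) - (1 - y) * np.log(1 - p)))


def _leaky_grad(a: np.ndarray) -> np.ndarray:
    return np.where(a >= 0, 1.0, 0.2)


def _dnn_backward(dlogits: np.ndarray, params: DNNParams, caches):
    """Backprop through the DNN; returns parameter grads and input grad."""
    grads = {
        "W": [None] * params.n_layers,
        "b": [None] * params.n_layers,
        "gamma": [None] * (params.n_layers - 1),
        "beta": [None] * (params.n_layers - 1),
    }
    h_last = caches[-1]["h_in"]
    grads["W"][-1] = h_last.T @ dlogits
    grads["b"][-1] = dlogits.sum(axis=0)
    dh = dlogits @ params.layer_weights[-1].T

    m = dlogits.shape[0]
    for l in range(params.n_layers - 2, -1, -1):
        c = caches[l]
        da = dh * _leaky_grad(c["a"])
        grads["gamma"][l] = (da * c["z_hat"]).sum(axis=0)
        grads["beta"][l] = da.sum(axis=0)
        dz_hat = da * params.bn_gamma[l]
        # batch-norm backward through the batch statistics
        dz = (
            c["inv_std"]
            / m
            * (
                m * dz_hat
                - dz_hat.sum(axis=0)
                - c["z_hat"] * (dz_hat * c["z_hat"]).sum(axis=0)
            )
        )
        grads["W"][l] = c["h_in"].T @ dz
        grads["b"][l] = dz.sum(axis=0)
        dh = dz @ params.layer_weights[l].T
    return grads, dh


def _gcn_forward_cached(a: np.ndarray, x: np.ndarray, gcn: GCNParams):
    """Full-graph encoder forward with caches for backprop."""
    h = x
    caches = []
    for w in gcn.layer_weights:
        msg = a @ h  # (n, d_in)
        z = msg @ w
        h_out = leaky_relu(z)
        caches.append({"msg": msg, "z": z})
        h = h_out
    return h, caches


def _gcn_backward(dh_full: np.ndarray, a: np.ndarray, gcn: GCNParams, caches):
    grads = [None] * gcn.n_layers
    dh = dh_full
    for l in range(gcn.n_layers - 1, -1, -1):
        c = caches[l]
        dz = dh * _leaky_grad(c["z"])
        grads[l] = c["msg"].T @ dz
        dh = a.T @ (dz @ gcn.layer_weights[l].T)
    return grads, dh


def loss_and_grads(
    a: np.ndarray,
    x: np.ndarray | None,
    dw: np.ndarray | None,
    gcn: GCNParams | None,
    dnn: DNNParams,
    rows: np.ndarray,
    y: np.ndarray,
    raw: np.ndarray | None = None,
    training: bool = True,
    update_running: bool = False,
):
    """Joint loss and analytic gradients of the full encoder + classifier.

    Blocks present (walk embedding ``dw``, encoder on ``x`` through
    ``gcn``, raw features ``raw``) are concatenated per node; the loss
    is the mean binary cross-entropy on the ``rows`` of that fused
    matrix against labels ``y``. Returns ``(loss, gcn_grads, dnn_grads,
    probs)``.
    """
    blocks = []
    gcn_caches = None
    h_gcn = None
    if dw is not None:
        blocks.append(dw[rows])
    if gcn is not None:
        if x is None:
            raise ValueError("encoder branch requires node features")
        h_gcn, gcn_caches = _gcn_forward_cached(a, x, gcn)
        blocks.append(h_gcn[rows])
    if raw is not None:
        blocks.append(raw[rows])
    if not blocks:
        raise ValueError("no input blocks")
    fused = np.concatenate(blocks, axis=1)

    probs, caches = _dnn_forward_cached(
        fused, dnn, training=training, update_running=update_running
    )
    p = probs[:, 1]
    loss = bce_loss(y, p)

    m = len(y)
    # d(mean BCE)/dlogits through the two-class softmax: (p - y)/m on the
    # positive logit, the negative on the other (clipping rarely binds)
    dl1 = (p - y) / m
    dlogits = np.stack([-dl1, dl1], axis=1)
    dnn_grads, dfused = _dnn_backward(dlogits, dnn, caches)

    gcn_grads = None
    offset = 0
    if dw is not None:
        offset += dw.shape[1]
    if gcn is not None:
        d_gc = dfused[:, offset: offset + h_gcn.shape[1]]
        dh_full = np.zeros_like(h_gcn)
        dh_full[rows] = d_gc
        gcn_grads, _ = _gcn_backward(dh_full, a, gcn, gcn_caches)
    return loss, gcn_grads, dnn_grads, probs


class _Adam:
    """Adam with the usual defaults over a flat list of arrays."""

    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


@dataclass
class TrainedModel:
    """Fitted encoder + classifier bound to the network it was trained on."""

    node_ids: tuple[str, ...]
    a_hat: np.ndarray
    features: np.ndarray | None
    dw_vectors: np.ndarray | None
    raw_features: np.ndarray | None
    gcn_params: GCNParams | None
    dnn_params: DNNParams
    log: list[dict]
    best_epoch: int = 0


def train_model(
    net: GeneNetwork,
    x: NodeFeatureMatrix | None,
    dw: EmbeddingMatrix | None,
    labels: dict[str, int],
    cfg: TrainingConfig,
    *,
    use_gcn: bool = True,
    use_deepwalk: bool = True,
    use_raw_features: bool = False,
    gcn_layers: int = 3,
    gcn_hidden: int = 64,
    hidden_widths: tuple[int, ...] = (64, 32),
) -> TrainedModel:
    """Jointly fit the convolutional encoder and the prediction DNN.

    The ablation variants are selected by the ``use_*`` flags: the full
    model fuses walk embeddings with the encoder output; dropping the
    encoder leaves the frozen walk embeddings; dropping the walk branch
    leaves the encoder; ``use_raw_features`` feeds node features
    straight to the DNN with no graph information.

    Early stopping monitors binary cross-entropy on a stratified
    held-out validation split of the labelled nodes and the parameters
    at the best validation epoch are returned.
    """
    labelled = [g for g in labels if g in net._index]
    if len(labelled) != len(labels):
        missing = sorted(set(labels) - set(net.node_ids))
        raise ValueError(f"labelled nodes absent from network: {missing}")
    labelled = sorted(labels)
    y_all = np.array([labels[g] for g in labelled], dtype=np.float64)
    if len(np.unique(y_all)) < 2:
        raise ValueError("degenerate training set: only one class present")

    if use_gcn or use_raw_features:
        if x is None:
            raise ValueError("node features required for this variant")
        if x.node_ids != net.node_ids:
            raise ValueError("feature node order must match network")
    if use_deepwalk:
        if dw is None:
            raise ValueError("walk embeddings required for this variant")
        if dw.node_ids != net.node_ids:
            raise ValueError("embedding node order must match network")
    if not (use_gcn or use_deepwalk or use_raw_features):
        raise ValueError("at least one input branch required")

    rng_seed = int(cfg.seed) % (2**31)
    a = normalize_adjacency(net).matrix
    rows_all = np.array([net.index_of(g) for g in labelled])

    tr, va = train_test_split(
        np.arange(len(labelled)),
        test_size=cfg.validation_fraction,
        stratify=y_all,
        random_state=rng_seed,
    )
    rows_tr, y_tr = rows_all[tr], y_all[tr]
    rows_va, y_va = rows_all[va], y_all[va]

    feat = x.features if x is not None else None
    dw_vec = dw.vectors if (use_deepwalk and dw is not None) else None
    raw = feat if use_raw_features else None
    gcn_feat = feat if use_gcn else None

    input_dim = 0
    if dw_vec is not None:
        input_dim += dw_vec.shape[1]
    if use_gcn:
        input_dim += gcn_hidden
    if raw is not None:
        input_dim += raw.shape[1]

    gcn_params = (
        init_gcn_params(feat.shape[1], gcn_hidden, gcn_layers, seed=rng_seed)
        if use_gcn
        else None
    )
    dnn_params = init_dnn_params(input_dim, hidden_widths, seed=rng_seed + 1)

    def flat_params():
        ps = list(gcn_params.layer_weights) if gcn_params is not None else []
        ps += dnn_params.layer_weights + dnn_params.layer_biases
        ps += dnn_params.bn_gamma + dnn_params.bn_beta
        return ps

    opt = _Adam(flat_params(), lr=cfg.learning_rate)
    rng = np.random.default_rng(rng_seed + 2)

    def val_loss() -> float:
        loss, *_ = loss_and_grads(
            a, gcn_feat, dw_vec, gcn_params, dnn_params, rows_va, y_va,
            raw=raw, training=False,
        )
        return loss

    best = {
        "loss": np.inf,
        "epoch": -1,
        "gcn": None,
        "dnn": None,
    }
    log: list[dict] = []
    since_best = 0
    for epoch in range(cfg.max_epochs):
        if cfg.batch_size is None:
            batches = [np.arange(len(rows_tr))]
        else:
            order = rng.permutation(len(rows_tr))
            batches = [
                order[i: i + cfg.batch_size]
                for i in range(0, len(order), cfg.batch_size)
            ]
            batches = [b for b in batches if len(b) >= 2]
        epoch_loss = 0.0
        for b in batches:
            loss, gcn_grads, dnn_grads, _ = loss_and_grads(
                a, gcn_feat, dw_vec, gcn_params, dnn_params,
                rows_tr[b], y_tr[b], raw=raw,
                training=True, update_running=True,
            )
            epoch_loss += loss * len(b)
            gs = list(gcn_grads) if gcn_grads is not None else []
            gs += dnn_grads["W"] + dnn_grads["b"]
            gs += dnn_grads["gamma"] + dnn_grads["beta"]
            opt.step(flat_params(), gs)
        epoch_loss /= len(rows_tr)

        vl = val_loss()
        log.append({"epoch": epoch, "train_loss": epoch_loss, "val_loss": vl})
        if vl < best["loss"]:
            best = {
                "loss": vl,
                "epoch": epoch,
                "gcn": copy.deepcopy(gcn_params),
                "dnn": copy.deepcopy(dnn_params),
            }
            since_best = 0
        else:
            since_best += 1
            if since_best > cfg.patience_epochs:
                break

    return TrainedModel(
        node_ids=net.node_ids,
        a_hat=a,
        features=feat,
        dw_vectors=dw_vec,
        raw_features=raw,
        gcn_params=best["gcn"],
        dnn_params=best["dnn"],
        log=log,
        best_epoch=best["epoch"],
    )


def _all_probs(model: TrainedModel) -> np.ndarray:
    """Inference-mode positive-class probability for every network node."""
    rows = np.arange(len(model.node_ids))
    y_dummy = np.zeros(len(rows))
    _, _, _, probs = loss_and_grads(
        model.a_hat,
        model.features if model.gcn_params is not None else None,
        model.dw_vectors,
        model.gcn_params,
        model.dnn_params,
        rows,
        y_dummy,
        raw=model.raw_features,
        training=False,
    )
    return probs[:, 1]


def score_nodes(model: TrainedModel, nodes) -> np.ndarray:
    """Positive-class probability for the given nodes (inference mode)."""
    index = {g: i for i, g in enumerate(model.node_ids)}
    try:
        rows = [index[g] for g in nodes]
    except KeyError as e:
        raise KeyError(f"unknown node {e.args[0]!r}") from None
    return _all_probs(model)[rows]


def predict(model: TrainedModel, nodes) -> list[Prediction]:
    """Score nodes and attach the argmax label (ties go to the positive class)."""
    p = score_nodes(model, nodes)
    return [
        Prediction(node_id=g, probability_positive=float(pi), label=int(pi >= 0.5))
        for g, pi in zip(nodes, p)
    ]


def save_model(path, model: TrainedModel) -> None:
    """Persist a fitted model (all parameters + bound inputs) as one archive."""
    arrays: dict[str, np.ndarray] = {
        "node_ids": np.array(model.node_ids),
        "a_hat": model.a_hat,
        "best_epoch": np.array(model.best_epoch),
        "has_gcn": np.array(model.gcn_params is not None),
        "has_dw": np.array(model.dw_vectors is not None),
        "has_raw": np.array(model.raw_features is not None),
    }
    if model.features is not None:
        arrays["features"] = model.features
    if model.dw_vectors is not None:
        arrays["dw_vectors"] = model.dw_vectors
    if model.gcn_params is not None:
        for i, w in enumerate(model.gcn_params.layer_weights):
            arrays[f"gcn_w{i}"] = w
    d = model.dnn_params
    for name, lst in (
        ("dnn_w", d.layer_weights), ("dnn_b", d.layer_biases),
        ("bn_gamma", d.bn_gamma), ("bn_beta", d.bn_beta),
        ("bn_mean", d.bn_mean), ("bn_var", d.bn_var),
    ):
        for i, arr in enumerate(lst):
            arrays[f"{name}{i}"] = arr
    np.savez(path, **arrays)


def load_model(path) -> TrainedModel:
    from .gcn import GCNParams  # local import to avoid cycle confusion

    with np.load(path, allow_pickle=False) as z:
        def series(prefix):
            out = []
            i = 0
            while f"{prefix}{i}" in z:
                out.append(z[f"{prefix}{i}"])
                i += 1
            return out

        gcn = GCNParams(layer_weights=series("gcn_w")) if bool(z["has_gcn"]) else None
        dnn = DNNParams(
            layer_weights=series("dnn_w"),
            layer_biases=series("dnn_b"),
            bn_gamma=series("bn_gamma"),
            bn_beta=series("bn_beta"),
            bn_mean=series("bn_mean"),
            bn_var=series("bn_var"),
        )
        features = z["features"] if "features" in z else None
        dw = z["dw_vectors"] if bool(z["has_dw"]) else None
        return TrainedModel(
            node_ids=tuple(str(g) for g in z["node_ids"]),
            a_hat=z["a_hat"],
            features=features,
            dw_vectors=dw,
            raw_features=features if bool(z["has_raw"]) else None,
            gcn_params=gcn,
            dnn_params=dnn,
            log=[],
            best_epoch=int(z["best_epoch"]),
        )
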