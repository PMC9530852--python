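"""Cross-validated evaluation, ranking metrics, ablations and the RWR baseline.

The protocol is repeated stratified 10-fold cross-validation: the
labelled genes are partitioned into 10 stratified folds, each fold in
turn is held out as the test set while the rest train the model, and
the whole procedure is repeated with fresh partitions. Ranking quality
is summarized by AUROC (probability that a random positive outranks a
random negative, ties half-credited) and AUPR (area under the
precision-recall step curve, no interpolation); the final figures are
arithmetic means over all folds of all repeats.

Methods available to the runner:

* ``deepRW`` — walk embedding + convolutional encoder, fused, DNN.
* ``withoutGCN`` — walk embedding only, DNN.
* ``withoutDeepWalk`` — convolutional encoder only, DNN.
* ``dnnOnly`` — raw node features straight to the DNN (no graph).
* ``rwr`` — random walk with restart from the training-fold positives;
  a test gene's score is its stationary visiting probability, i.e. its
  network proximity to the known disease genes. Needs no training.

Walk embeddings are unsupervised and label-free, so they are trained
once per dataset and shared across folds and repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from . import classifier as clf
from .deepwalk import generate_walks, train_skipgram
from .embeddings import EmbeddingMatrix
from .gcn import NodeFeatureMatrix
from .graph import GeneNetwork

__all__ = [
    "FoldAssignment",
    "EvalReport",
    "METHODS",
    "stratified_kfold",
    "auroc",
    "aupr",
    "rwr_scores",
    "run_cv",
    "layer_ablation",
    "relative_difference",
]

METHODS = ("deepRW", "withoutGCN", "withoutDeepWalk", "dnnOnly", "rwr")


@dataclass(frozen=True)
class FoldAssignment:
    """One stratified partition of the labelled genes into k folds."""

    k: int
    repeat_index: int
    folds: dict[str, int]  # node -> fold index
    seed: int

    def test_nodes(self, fold: int) -> list[str]:
        return sorted(g for g, f in self.folds.items() if f == fold)

    def train_nodes(self, fold: int) -> list[str]:
        return sorted(g for g, f in self.folds.items() if f != fold)


@dataclass
class EvalReport:
    """Per-fold and aggregate ranking metrics for one method."""

    method: str
    auroc_folds: list[list[float]] = field(default_factory=list)  # [repeat][fold]
    aupr_folds: list[list[float]] = field(default_factory=list)

    @property
    def mean_auroc(self) -> float:
        return float(np.mean([v for rep in self.auroc_folds for v in rep]))

    @property
    def mean_aupr(self) -> float:
        return float(np.mean([v for rep in self.aupr_folds for v in rep]))

    @property
    def n_folds_total(self) -> int:
        return sum(len(rep) for rep in self.auroc_folds)


def stratified_kfold(
    labels: dict[str, int], k: int = 10, repeats: int = 10, seed: int = 0
) -> list[FoldAssignment]:
    """One independent stratified k-fold partition per repeat, seeded.

    Within each class the fold sizes differ by at most one; the folds
    receiving a class's remainder are staggered across classes so the
    overall fold sizes also differ by at most one.
    """
    nodes = sorted(labels)
    y = np.array([labels[g] for g in nodes])
    classes = sorted(np.unique(y).tolist())
    for cls in classes:
        if int((y == cls).sum()) < k:
            raise ValueError(f"class {cls} has fewer than k={k} members")
    rng = np.random.default_rng(seed)
    out = []
    for r in range(repeats):
        folds: dict[str, int] = {}
        offset = 0
        for cls in classes:
            members = [nodes[i] for i in np.flatnonzero(y == cls)]
            perm = rng.permutation(len(members))
            base, rem = divmod(len(members), k)
            pos = 0
            for f in range(k):
                size = base + (1 if (f - offset) % k < rem else 0)
                for _ in range(size):
                    folds[members[perm[pos]]] = f
                    pos += 1
            offset += rem
        out.append(FoldAssignment(k=k, repeat_index=r, folds=folds, seed=seed))
    return out


def auroc(scores, labels) -> float:
    """Probability a random positive outranks a random negative; ties count 1/2."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=np.float64)))


def aupr(scores, labels) -> float:
    """Area under the precision-recall step curve (no interpolation)."""
    labels = np.asarray(labels)
    if not np.any(labels == 1):
        raise ValueError("AUPR needs at least one positive")
    return float(average_precision_score(labels, np.asarray(scores, dtype=np.float64)))


def rwr_scores(
    net: GeneNetwork,
    seed_nodes,
    restart_prob: float = 0.5,
    tol: float = 1e-10,
    max_iter: int = 10000,
) -> dict[str, float]:
    """Random walk with restart: stationary proximity to the seed set.

    Solves p = (1 - r) P^T p + r e by power iteration, with P the
    row-normalized transition matrix of the weighted network and e
    uniform over the seeds; iterates until the L1 change is below
    ``tol``. The result is a probability distribution over nodes.
    """
    seed_nodes = list(seed_nodes)
    if not seed_nodes:
        raise ValueError("RWR needs at least one seed node")
    if not 0.0 < restart_prob <= 1.0:
        raise ValueError("restart_prob must be in (0, 1]")
    idx = [net.index_of(g) for g in seed_nodes]
    n = net.n_nodes
    e = np.zeros(n)
    e[idx] = 1.0 / len(idx)

    deg = net.degrees()
    pt = (net.adjacency / deg[:, None]).T  # column-stochastic P^T
    p = e.copy()
    for _ in range(max_iter):
        p_new = (1.0 - restart_prob) * (pt @ p) + restart_prob * e
        if np.abs(p_new - p).sum() < tol:
            p = p_new
            break
        p = p_new
    return {g: float(p[i]) for i, g in enumerate(net.node_ids)}


def relative_difference(reference: float, other: float) -> float:
    """Percentage by which ``other`` falls short of ``reference``."""
    if reference <= 0:
        raise ValueError("reference must be > 0")
    return 100.0 * (reference - other) / reference


@dataclass(frozen=True)
class DataBundle:
    """Network + node features + labelled gene set, the CV input."""

    net: GeneNetwork
    features: NodeFeatureMatrix | None
    labels: dict[str, int]


def _deepwalk_embedding(
    net: GeneNetwork,
    seed: int,
    dim: int,
    window: int,
    iterations: int,
    walks_per_node: int,
    walk_length: int,
) -> EmbeddingMatrix:
    corpus = generate_walks(net, walks_per_node, walk_length, seed=seed)
    return train_skipgram(
        corpus, dim, window=window, iterations=iterations,
        seed=seed + 1, node_ids=net.node_ids,
    )


def run_cv(
    method: str,
    bundle: DataBundle,
    *,
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
    gcn_layers: int = 3,
    gcn_hidden: int = 64,
    hidden_widths: tuple[int, ...] = (64, 32),
    embedding_dim: int = 64,
    window: int = 10,
    skipgram_iterations: int = 10,
    walks_per_node: int = 10,
    walk_length: int = 40,
    restart_prob: float = 0.5,
    training: clf.TrainingConfig | None = None,
    dw: EmbeddingMatrix | None = None,
) -> EvalReport:
    """Repeated stratified k-fold cross-validation of one method.

    For every repeat and fold the model is trained on the train folds
    and its scores on the held-out fold yield one (AUROC, AUPR) pair;
    the report carries all ``repeats * k`` pairs plus their means.
    ``dw`` lets a caller pass precomputed walk embeddings (they are
    label-free, so sharing them across methods and folds is sound);
    otherwise they are trained here when the method needs them.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    net, x, labels = bundle.net, bundle.features, bundle.labels
    missing = sorted(set(labels) - set(net.node_ids))
    if missing:
        raise ValueError(f"labelled genes absent from network: {missing}")

    needs_dw = method in ("deepRW", "withoutGCN")
    if needs_dw and dw is None:
        dw = _deepwalk_embedding(
            net, seed, embedding_dim, window, skipgram_iterations,
            walks_per_node, walk_length,
        )
    if training is None:
        training = clf.TrainingConfig(seed=seed)

    assignments = stratified_kfold(labels, k=k, repeats=repeats, seed=seed)
    report = EvalReport(method=method)
    for assign in assignments:
        rep_auroc: list[float] = []
        rep_aupr: list[float] = []
        for fold in range(k):
            test = assign.test_nodes(fold)
            train = assign.train_nodes(fold)
            y_test = np.array([labels[g] for g in test])
            if method == "rwr":
                seeds = [g for g in train if labels[g] == 1]
                prox = rwr_scores(net, seeds, restart_prob=restart_prob)
                scores = np.array([prox[g] for g in test])
            else:
                fold_cfg = clf.TrainingConfig(
                    max_epochs=training.max_epochs,
                    patience_epochs=training.patience_epochs,
                    learning_rate=training.learning_rate,
                    batch_size=training.batch_size,
                    seed=(training.seed + 977 * assign.repeat_index + fold) % (2**31),
                    validation_fraction=training.validation_fraction,
                )
                model = clf.train_model(
                    net, x, dw, {g: labels[g] for g in train}, fold_cfg,
                    use_gcn=method in ("deepRW", "withoutDeepWalk"),
                    use_deepwalk=method in ("deepRW", "withoutGCN"),
                    use_raw_features=method == "dnnOnly",
                    gcn_layers=gcn_layers,
                    gcn_hidden=gcn_hidden,
                    hidden_widths=hidden_widths,
                )
                scores = clf.score_nodes(model, test)
            rep_auroc.append(auroc(scores, y_test))
            rep_aupr.append(aupr(scores, y_test))
        report.auroc_folds.append(rep_auroc)
        report.aupr_folds.append(rep_aupr)
    return report


def layer_ablation(
    bundle: DataBundle, depths=(2, 3, 4), **kwargs
) -> dict[int, EvalReport]:
    """Cross-validate the full model at several encoder depths.

    Depth 3 is the package default: shallower encoders underuse the
    neighborhood and deeper ones begin to over-smooth.
    """
    return {
        d: run_cv("deepRW", bundle, gcn_layers=d, **kwargs) for d in depths
    }
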