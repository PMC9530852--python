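"""Train the full model on synthetic data and score individual genes.

Walk embeddings (unsupervised) and a convolutional encoding of node
features are fused and classified by the feed-forward network; the
encoder and classifier are trained jointly under binary cross-entropy
with early stopping on a held-out validation split. The script prints
the predicted probability of disease association for a few known
positive and known negative genes.
"""

import numpy as np

from deeprw import (
    SimulationConfig, TrainingConfig, generate_walks, predict,
    simulate_features, simulate_network, train_model, train_skipgram,
)

cfg = SimulationConfig(n_pos=60, n_neg=60, seed=5)
net, labels = simulate_network(cfg)
feats = simulate_features(labels, cfg)

corpus = generate_walks(net, walks_per_node=10, walk_length=40, seed=5)
dw = train_skipgram(corpus, dim=32, window=10, iterations=10, seed=6,
                    node_ids=net.node_ids)

model = train_model(
    net, feats, dw, labels,
    TrainingConfig(max_epochs=100, patience_epochs=20, seed=7),
    gcn_hidden=32, hidden_widths=(32, 16),
)
print(f"trained {len(model.log)} epochs; best validation loss at epoch "
      f"{model.best_epoch} "
      f"({model.log[model.best_epoch]['val_loss']:.4f})")

rng = np.random.default_rng(1)
pos = rng.choice([g for g, y in labels.items() if y == 1], 3, replace=False)
neg = rng.choice([g for g, y in labels.items() if y == 0], 3, replace=False)
print("\ngene    true class  P(disease-associated)")
for g in [*pos, *neg]:
    p = predict(model, [g])[0]
    print(f"{g}   {labels[g]}           {p.probability_positive:.3f}")
print("\nHigh probabilities for class-1 genes and low for class-0 genes "
      "indicate the fused representation separates the classes.")
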