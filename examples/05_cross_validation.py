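"""Compare the full model, its ablations and the RWR baseline by CV.

Stratified 10-fold cross-validation on a strong-signal synthetic
dataset at reduced size (40+40 genes, 2 repeats to keep the run
short). The ablations drop one representation branch each: withoutGCN
keeps only walk embeddings, withoutDeepWalk only the convolutional
encoder, dnnOnly feeds raw features to the classifier, and rwr ranks
genes by network proximity to the training positives. Mean AUROC and
AUPR over all folds are printed, plus the percentage by which the
baseline trails the full model.
"""

from deeprw import (
    DataBundle, METHODS, SimulationConfig, TrainingConfig, generate_walks,
    relative_difference, run_cv, simulate_features, simulate_network,
    train_skipgram,
)

cfg = SimulationConfig(n_pos=40, n_neg=40, seed=11)
net, labels = simulate_network(cfg)
bundle = DataBundle(net=net, features=simulate_features(labels, cfg), labels=labels)

corpus = generate_walks(net, walks_per_node=10, walk_length=40, seed=11)
dw = train_skipgram(corpus, dim=32, window=10, iterations=10, seed=12,
                    node_ids=net.node_ids)

training = TrainingConfig(max_epochs=60, patience_epochs=15, seed=0)
reports = {}
print("method            mean AUROC  mean AUPR   (1.0 = perfect ranking of held-out genes)")
for method in METHODS:
    rep = run_cv(method, bundle, k=10, repeats=2, seed=13, dw=dw,
                 gcn_hidden=32, hidden_widths=(32, 16), embedding_dim=32,
                 training=training)
    reports[method] = rep
    print(f"{method:<16}  {rep.mean_auroc:.3f}       {rep.mean_aupr:.3f}")

gap = relative_difference(reports["deepRW"].mean_auroc, reports["rwr"].mean_auroc)
print(f"\nRWR trails the full model by {gap:.2f}% in mean AUROC on this dataset.")
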