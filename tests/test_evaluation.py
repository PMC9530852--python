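"""Cross-validation harness, ranking metrics and the RWR baseline."""

import numpy as np
import pytest

import deeprw as d


def brute_force_auroc(scores, labels):
    """Mean over all positive-negative pairs of win=1 / tie=0.5 / loss=0."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def threshold_sweep_aupr(scores, labels):
    """Step-curve area: sum over distinct thresholds of dRecall * precision."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    area = 0.0
    prev_recall = 0.0
    for t in sorted(set(scores), reverse=True):
        sel = scores >= t
        tp = int((labels[sel] == 1).sum())
        precision = tp / sel.sum()
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


class TestStratifiedKFold:
    def test_fold_sizes_at_reference_scale(self):
        labels = {f"G{i:04d}": int(i <= 142) for i in range(1, 285)}
        for assign in d.stratified_kfold(labels, k=10, repeats=10, seed=4):
            for f in range(10):
                test = assign.test_nodes(f)
                assert len(test) in (28, 29)
                assert sum(labels[g] for g in test) in (14, 15)

    def test_folds_partition_the_labelled_set(self):
        labels = {f"N{i}": i % 2 for i in range(57)}
        for assign in d.stratified_kfold(labels, k=5, repeats=3, seed=0):
            seen = [g for f in range(5) for g in assign.test_nodes(f)]
            assert sorted(seen) == sorted(labels)  # disjoint union
            for f in range(5):
                assert set(assign.test_nodes(f)).isdisjoint(assign.train_nodes(f))

    def test_same_seed_reproduces_assignment(self):
        labels = {f"N{i}": i % 2 for i in range(40)}
        a1 = d.stratified_kfold(labels, k=4, repeats=2, seed=9)
        a2 = d.stratified_kfold(labels, k=4, repeats=2, seed=9)
        assert [a.folds for a in a1] == [a.folds for a in a2]

    def test_small_class_rejected(self):
        labels = {f"N{i}": int(i < 3) for i in range(30)}
        with pytest.raises(ValueError, match="fewer than k"):
            d.stratified_kfold(labels, k=10)


class TestAUROC:
    def test_perfect_separation(self):
        assert d.auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_constant_scores_are_chance(self):
        assert d.auroc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_worked_example(self):
        assert d.auroc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            d.auroc([0.1, 0.2], [1, 1])

    @pytest.mark.parametrize("seed", range(200))
    def test_matches_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 31))
        labels = np.zeros(n, int)
        labels[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        scores = np.round(rng.random(n), 2)  # coarse grid induces ties
        assert abs(d.auroc(scores, labels) - brute_force_auroc(scores, labels)) < 1e-12


class TestAUPR:
    def test_perfect_ranking(self):
        assert d.aupr([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_single_positive_ranked_last(self):
        n = 5
        scores = [0.9, 0.8, 0.7, 0.6, 0.5]
        labels = [0, 0, 0, 0, 1]
        assert d.aupr(scores, labels) == pytest.approx(1 / n)

    def test_no_positive_rejected(self):
        with pytest.raises(ValueError, match="at least one positive"):
            d.aupr([0.1, 0.2], [0, 0])

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_threshold_sweep_oracle(self, seed):
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(3, 21))
        labels = (rng.random(n) < 0.4).astype(int)
        if labels.sum() == 0:
            labels[0] = 1
        scores = np.round(rng.random(n), 1)
        assert abs(
            d.aupr(scores, labels) - threshold_sweep_aupr(scores, labels)
        ) < 1e-10


class TestRWR:
    def test_restart_one_returns_seed_distribution(self, path_net):
        scores = d.rwr_scores(path_net, ["A"], restart_prob=1.0)
        assert scores == pytest.approx({"A": 1.0, "B": 0.0, "C": 0.0})

    def test_two_node_closed_form(self, two_node_net):
        scores = d.rwr_scores(two_node_net, ["A"], restart_prob=0.5)
        assert scores["A"] == pytest.approx(2 / 3, abs=1e-9)
        assert scores["B"] == pytest.approx(1 / 3, abs=1e-9)

    def test_scores_form_a_distribution_at_fixed_point(self, two_clique_net):
        net = two_clique_net
        scores = d.rwr_scores(net, ["A00", "A01"], restart_prob=0.3)
        p = np.array([scores[g] for g in net.node_ids])
        assert p.sum() == pytest.approx(1.0, abs=1e-9)
        e = np.zeros(net.n_nodes)
        for g in ("A00", "A01"):
            e[net.index_of(g)] = 0.5
        pt = (net.adjacency / net.degrees()[:, None]).T
        residual = np.abs(0.7 * (pt @ p) + 0.3 * e - p).sum()
        assert residual < 1e-9

    def test_no_seeds_rejected(self, path_net):
        with pytest.raises(ValueError, match="seed"):
            d.rwr_scores(path_net, [])

    def test_proximity_concentrates_near_seeds(self, two_clique_net):
        scores = d.rwr_scores(two_clique_net, ["A03"], restart_prob=0.5)
        a_side = np.mean([v for g, v in scores.items() if g.startswith("A")])
        b_side = np.mean([v for g, v in scores.items() if g.startswith("B")])
        assert a_side > b_side


class TestRelativeDifference:
    def test_identical_values_give_zero(self):
        assert d.relative_difference(0.7, 0.7) == 0.0

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            d.relative_difference(0.0, 0.5)

    def test_percentage_scale(self):
        assert d.relative_difference(1.0, 0.75) == pytest.approx(25.0)


class TestRunCV:
    def test_report_contains_all_repeat_fold_pairs(self, small_bundle):
        rep = d.run_cv("rwr", small_bundle, k=10, repeats=10, seed=2)
        assert rep.n_folds_total == 100
        flat = [v for r in rep.auroc_folds for v in r]
        assert all(0.0 <= v <= 1.0 for v in flat)
        assert 0.0 <= rep.mean_aupr <= 1.0

    def test_unknown_method_rejected(self, small_bundle):
        with pytest.raises(ValueError, match="unknown method"):
            d.run_cv("magic", small_bundle)

    def test_dnn_only_ignores_network_structure(self, small_bundle, fast_training):
        """Rewiring the graph must not change feature-only predictions."""
        other_cfg = d.SimulationConfig(
            n_pos=30, n_neg=30, p_in=0.25, p_out=0.04,
            feature_effect=1.5, noise_sd=1.0, n_features=12, seed=99,
        )
        other_net, _ = d.simulate_network(other_cfg)
        rewired = d.DataBundle(
            net=other_net, features=small_bundle.features, labels=small_bundle.labels
        )
        kw = dict(k=5, repeats=1, seed=5, training=fast_training)
        rep1 = d.run_cv("dnnOnly", small_bundle, **kw)
        rep2 = d.run_cv("dnnOnly", rewired, **kw)
        assert rep1.auroc_folds == rep2.auroc_folds
        assert rep1.aupr_folds == rep2.aupr_folds

    def test_layer_ablation_returns_report_per_depth(self, small_bundle, fast_training):
        reports = d.layer_ablation(
            small_bundle, depths=(2, 3), k=5, repeats=1, seed=6,
            training=fast_training, gcn_hidden=16, hidden_widths=(8,),
            embedding_dim=16, walks_per_node=4, walk_length=10,
            skipgram_iterations=2,
        )
        assert sorted(reports) == [2, 3]
        for rep in reports.values():
            assert rep.n_folds_total == 5
            assert 0.0 <= rep.mean_auroc <= 1.0
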