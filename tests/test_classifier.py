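"""Fusion, DNN forward pass, loss, gradients and joint training."""

from decimal import Decimal, getcontext

import numpy as np
import pytest

import deeprw as d
from deeprw.classifier import init_dnn_params, loss_and_grads
from deeprw.gcn import init_gcn_params


def make_emb(ids, vectors):
    return d.EmbeddingMatrix(node_ids=tuple(ids), vectors=np.asarray(vectors, float))


class TestFuse:
    def test_concatenation_dims_and_blocks(self):
        rng = np.random.default_rng(0)
        ids = ["A", "B", "C"]
        dw = make_emb(ids, rng.standard_normal((3, 4)))
        gc = make_emb(ids, rng.standard_normal((3, 2)))
        fused = d.fuse(dw, gc)
        assert fused.dim == 6
        np.testing.assert_array_equal(fused.vectors[:, :4], dw.vectors)
        np.testing.assert_array_equal(fused.vectors[:, 4:], gc.vectors)

    def test_zero_dim_second_block_is_identity(self):
        ids = ["A", "B"]
        dw = make_emb(ids, np.ones((2, 3)))
        empty = make_emb(ids, np.zeros((2, 0)))
        np.testing.assert_array_equal(d.fuse(dw, empty).vectors, dw.vectors)

    def test_node_order_mismatch_raises(self):
        dw = make_emb(["A", "B"], np.ones((2, 2)))
        gc = make_emb(["B", "A"], np.ones((2, 2)))
        with pytest.raises(ValueError, match="node order"):
            d.fuse(dw, gc)


class TestDNNForward:
    def test_rows_sum_to_one(self):
        params = init_dnn_params(5, (4, 3), seed=0)
        x = np.random.default_rng(1).standard_normal((7, 5))
        probs = d.dnn_forward(x, params)
        np.testing.assert_allclose(probs.sum(axis=1), np.ones(7), atol=1e-9)
        assert np.all(probs >= 0)

    def test_zero_final_logits_give_uniform_softmax(self):
        params = init_dnn_params(3, (2,), seed=0)
        params.layer_weights[-1][:] = 0.0
        params.layer_biases[-1][:] = 0.0
        probs = d.dnn_forward(np.random.default_rng(2).standard_normal((4, 3)), params)
        np.testing.assert_allclose(probs, 0.5 * np.ones((4, 2)))

    def test_inference_mode_is_deterministic(self):
        params = init_dnn_params(4, (3,), seed=1)
        x = np.random.default_rng(3).standard_normal((6, 4))
        np.testing.assert_array_equal(
            d.dnn_forward(x, params, training_mode=False),
            d.dnn_forward(x, params, training_mode=False),
        )

    def test_input_dim_mismatch_raises(self):
        params = init_dnn_params(4, (3,), seed=1)
        with pytest.raises(ValueError, match="incompatible"):
            d.dnn_forward(np.zeros((2, 5)), params)


class TestBCELoss:
    @pytest.mark.parametrize(
        "y,p,expected",
        [
            (1, 1.0 - 1e-9, 0.0),
            (1, 0.5, np.log(2)),
            (0, 0.5, np.log(2)),
        ],
    )
    def test_known_values(self, y, p, expected):
        assert d.bce_loss(y, p) == pytest.approx(expected, abs=1e-6)

    def test_matches_arbitrary_precision_oracle(self):
        getcontext().prec = 50
        rng = np.random.default_rng(9)
        ys = rng.integers(0, 2, 1000)
        ps = rng.uniform(1e-6, 1 - 1e-6, 1000)
        for y, p in zip(ys, ps):
            dp = Decimal(repr(float(p)))
            exact = -Decimal(int(y)) * dp.ln() - Decimal(int(1 - y)) * (1 - dp).ln()
            assert d.bce_loss(int(y), float(p)) == pytest.approx(
                float(exact), abs=1e-9
            )

    def test_saturated_probabilities_stay_finite(self):
        assert np.isfinite(d.bce_loss(1, 0.0))
        assert np.isfinite(d.bce_loss(0, 1.0))


class TestGradients:
    def test_analytic_matches_finite_differences(self):
        """Joint encoder + classifier gradient on a 6-node toy problem."""
        net = d.build_network(
            [("A", "B", 1.0), ("B", "C", 0.5), ("C", "D", 2.0),
             ("D", "E", 1.0), ("E", "F", 0.3), ("A", "F", 0.7)]
        )
        a = d.normalize_adjacency(net).matrix
        rng = np.random.default_rng(0)
        x = rng.standard_normal((6, 4))
        dw = rng.standard_normal((6, 3))
        gcn = init_gcn_params(4, 5, 2, seed=1)
        dnn = init_dnn_params(8, (4,), seed=2)
        rows = np.arange(6)
        y = np.array([1, 0, 1, 0, 1, 0], float)

        def loss():
            val, *_ = loss_and_grads(a, x, dw, gcn, dnn, rows, y, training=True)
            return val

        _, ggcn, gdnn, _ = loss_and_grads(a, x, dw, gcn, dnn, rows, y, training=True)
        eps = 1e-6
        pairs = list(zip(gcn.layer_weights, ggcn))
        pairs += list(zip(dnn.layer_weights, gdnn["W"]))
        pairs += list(zip(dnn.layer_biases, gdnn["b"]))
        pairs += list(zip(dnn.bn_gamma, gdnn["gamma"]))
        pairs += list(zip(dnn.bn_beta, gdnn["beta"]))
        rng2 = np.random.default_rng(42)
        for arr, grad in pairs:
            flat = arr.reshape(-1)
            gflat = np.asarray(grad).reshape(-1)
            for i in rng2.choice(flat.size, size=min(8, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp = loss()
                flat[i] = orig - eps
                lm = loss()
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                denom = max(1e-8, abs(num) + abs(gflat[i]))
                assert abs(num - gflat[i]) / denom < 1e-4


class TestTrainModel:
    def test_separable_data_reaches_training_auroc_one(self, small_bundle):
        nodes = sorted(small_bundle.labels)
        y = np.array([small_bundle.labels[g] for g in nodes])
        for seed in range(3):
            cfg = d.TrainingConfig(max_epochs=80, patience_epochs=20, seed=seed)
            model = d.train_model(
                small_bundle.net, small_bundle.features, None,
                small_bundle.labels, cfg,
                use_gcn=False, use_deepwalk=False, use_raw_features=True,
            )
            scores = d.score_nodes(model, nodes)
            assert d.auroc(scores, y) >= 0.98

    def test_patience_zero_stops_at_first_non_improving_epoch(self, small_bundle):
        cfg = d.TrainingConfig(max_epochs=500, patience_epochs=0, seed=1)
        model = d.train_model(
            small_bundle.net, small_bundle.features, None, small_bundle.labels,
            cfg, use_gcn=False, use_deepwalk=False, use_raw_features=True,
        )
        vals = [e["val_loss"] for e in model.log]
        if len(vals) < 500:  # stopped early: only the last epoch failed to improve
            for i in range(1, len(vals) - 1):
                assert vals[i] < min(vals[:i])
            assert vals[-1] >= min(vals[:-1])

    def test_checkpoint_has_minimum_validation_loss(self, small_bundle, fast_training):
        model = d.train_model(
            small_bundle.net, small_bundle.features, None, small_bundle.labels,
            fast_training, use_gcn=False, use_deepwalk=False, use_raw_features=True,
        )
        vals = [e["val_loss"] for e in model.log]
        assert vals[model.best_epoch] == min(vals)

    def test_single_class_labels_rejected(self, small_bundle, fast_training):
        labels = {g: 1 for g in list(small_bundle.labels)[:20]}
        with pytest.raises(ValueError, match="degenerate training set"):
            d.train_model(
                small_bundle.net, small_bundle.features, None, labels,
                fast_training, use_gcn=False, use_deepwalk=False,
                use_raw_features=True,
            )


@pytest.fixture(scope="module")
def model(small_bundle):
    cfg = d.TrainingConfig(max_epochs=40, patience_epochs=10, seed=3)
    return d.train_model(
        small_bundle.net, small_bundle.features, None, small_bundle.labels,
        cfg, use_gcn=True, use_deepwalk=False, gcn_layers=2, gcn_hidden=16,
        hidden_widths=(8,),
    )


class TestPredict:
    def test_probabilities_and_labels_consistent(self, model, small_bundle):
        preds = d.predict(model, sorted(small_bundle.labels)[:15])
        for p in preds:
            assert 0.0 <= p.probability_positive <= 1.0
            assert p.label == int(p.probability_positive >= 0.5)

    def test_repeated_calls_identical(self, model, small_bundle):
        nodes = sorted(small_bundle.labels)[:10]
        p1 = [p.probability_positive for p in d.predict(model, nodes)]
        p2 = [p.probability_positive for p in d.predict(model, nodes)]
        assert p1 == p2

    def test_unknown_node_raises(self, model):
        with pytest.raises(KeyError, match="GHOST"):
            d.predict(model, ["GHOST"])

    def test_save_load_round_trip(self, model, small_bundle, tmp_path):
        path = tmp_path / "model.npz"
        d.save_model(path, model)
        back = d.load_model(path)
        nodes = sorted(small_bundle.labels)
        np.testing.assert_allclose(
            d.score_nodes(back, nodes), d.score_nodes(model, nodes), atol=1e-12
        )
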