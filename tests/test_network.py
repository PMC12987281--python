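"""CNN-LSTM classifier: parameter accounting, gradients, training, metrics."""

import numpy as np
import pytest
from sklearn.metrics import precision_recall_fscore_support

from pneumyo.network import (ArchitectureSpec, CnnLstmClassifier,
                             TrainingConfig, build_model,
                             count_trainable_params, evaluate,
                             flat_size_bytes, macc_estimate,
                             metrics_from_confusion, train)
from pneumyo.pipeline import DatasetSplit

DEFAULT = ArchitectureSpec()


def _layer_sum_oracle(spec):
    """Independent per-layer tally of trainable parameters."""
    conv = spec.conv_filters * spec.conv_kernel * spec.input_channels + spec.conv_filters
    h1, h2 = spec.lstm_units
    lstm1 = 4 * (spec.conv_filters * h1 + h1 * h1 + h1)
    lstm2 = 4 * (h1 * h2 + h2 * h2 + h2)
    dense = h2 * spec.num_classes + spec.num_classes
    return conv, lstm1, lstm2, dense


class TestParameterAccounting:
    def test_default_layer_components(self):
        conv, lstm1, lstm2, dense = _layer_sum_oracle(DEFAULT)
        assert (conv, lstm1, lstm2, dense) == (240, 7008, 1776, 78)
        assert count_trainable_params(DEFAULT) == conv + lstm1 + lstm2 + dense == 9102

    def test_minimal_conv_contribution(self):
        small = ArchitectureSpec(conv_filters=1, conv_kernel=1, input_channels=1)
        base = ArchitectureSpec(conv_filters=1, conv_kernel=1, input_channels=1,
                                num_classes=DEFAULT.num_classes)
        conv, *_ = _layer_sum_oracle(small)
        assert conv == 2
        assert count_trainable_params(base) - sum(_layer_sum_oracle(base)[1:]) == 2

    def test_class_count_linearity(self):
        twelve = ArchitectureSpec(num_classes=12)
        in_dim = DEFAULT.lstm_units[-1]
        assert (count_trainable_params(twelve) - count_trainable_params(DEFAULT)
                == (in_dim + 1) * 6)

    def test_weight_arrays_match_closed_form_for_random_specs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            spec = ArchitectureSpec(
                window_length=int(rng.integers(20, 80)),
                conv_filters=int(rng.integers(4, 64)),
                conv_kernel=int(rng.integers(2, 8)),
                lstm_units=(int(rng.integers(4, 32)), int(rng.integers(4, 32))),
                num_classes=6,
            )
            model = CnnLstmClassifier(spec, seed=1)
            assert model.param_count() == count_trainable_params(spec)

    def test_flat_size(self):
        n = count_trainable_params(DEFAULT)
        assert flat_size_bytes(DEFAULT) == 4 * n
        assert flat_size_bytes(DEFAULT, bytes_per_weight=1) == n

    def test_macc_convention(self):
        # conv 47*48*4 + lstm 23*4*24*72 + 23*4*12*36 + dense 12*6
        assert macc_estimate(DEFAULT) == 9024 + 158_976 + 39_744 + 72


class TestBuildAndForward:
    def test_softmax_output(self, rng):
        model = build_model(DEFAULT, seed=0)
        probs = model.predict_proba(rng.normal(size=(5, 50)))
        assert probs.shape == (5, 6)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(np.isfinite(probs))

    def test_pooled_length_guard(self):
        with pytest.raises(ValueError):
            ArchitectureSpec(window_length=4, conv_kernel=4, pool_size=2)

    def test_gradients_match_finite_differences(self):
        spec = ArchitectureSpec(window_length=12, conv_filters=3, conv_kernel=3,
                                pool_size=2, lstm_units=(4, 3),
                                dropout_rate=0.0, num_classes=3)
        model = CnnLstmClassifier(spec, seed=1, labels=["a", "b", "c"])
        rng = np.random.default_rng(2)
        X = rng.normal(size=(4, 12))
        onehot = model._encode(["a", "b", "c", "a"])

        def loss():
            p, _ = model._forward(X)
            return -np.mean(np.sum(onehot * np.log(p + 1e-12), axis=1))

        probs, caches = model._forward(X)
        grads = model._backward(probs, onehot, caches)
        eps = 1e-6
        for key, arr in model.params.items():
            for _ in range(4):
                ix = tuple(rng.integers(0, s) for s in arr.shape)
                orig = arr[ix]
                arr[ix] = orig + eps
                lp = loss()
                arr[ix] = orig - eps
                lm = loss()
                arr[ix] = orig
                num = (lp - lm) / (2 * eps)
                assert grads[key][ix] == pytest.approx(num, rel=1e-3, abs=1e-7), key


def _separable_split(n_per_class=60, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(50) / 100.0
    a = np.sin(2 * np.pi * 2 * t)
    X, y = [], []
    for _ in range(n_per_class):
        X.append(a + 0.05 * rng.normal(size=50))
        y.append("osc")
        X.append(0.05 * rng.normal(size=50))
        y.append("flat")
    return DatasetSplit(np.array(X), np.array(y, dtype=object),
                        np.array(X[:4]), np.array(y[:4], dtype=object))


class TestTraining:
    def test_rejects_zero_epochs(self):
        with pytest.raises(ValueError):
            TrainingConfig(epochs=0)

    def test_label_outside_vocabulary_rejected(self):
        model = build_model(DEFAULT, seed=0)
        with pytest.raises(ValueError, match="vocabulary"):
            model.fit(np.zeros((2, 50)), ["walking", "flying"],
                      TrainingConfig(epochs=1, seed=0))

    def test_learns_separable_two_class_data(self):
        """Linearly separable oscillating-vs-flat windows reach 100% training
        accuracy within 20 epochs, and the loss history has one entry per epoch."""
        split = _separable_split()
        spec = ArchitectureSpec(num_classes=2)
        model = build_model(spec, seed=3, labels=["osc", "flat"])
        cfg = TrainingConfig(epochs=20, batch_size=16, seed=3)
        model, history = train(model, split, cfg)
        assert len(history["loss"]) == 20
        assert history["loss"][-1] < history["loss"][0]
        assert max(history["accuracy"]) == 1.0

    def test_training_is_deterministic(self):
        split = _separable_split(n_per_class=20)
        spec = ArchitectureSpec(num_classes=2)
        cfg = TrainingConfig(epochs=3, batch_size=16, seed=7)
        hists = []
        for _ in range(2):
            model = build_model(spec, seed=7, labels=["osc", "flat"])
            _, h = train(model, split, cfg)
            hists.append(h["loss"])
        assert hists[0] == hists[1]


class TestEvaluate:
    def test_perfect_predictions(self):
        labels = ("a", "b", "c")
        cm = np.diag([4, 5, 6])
        m = metrics_from_confusion(cm, labels)
        assert m.accuracy == 1.0
        assert all(s["f1"] == 1.0 for s in m.per_class.values())

    def test_single_class_predictor_on_balanced_data(self):
        cm = np.zeros((6, 6), dtype=int)
        cm[:, 0] = 10
        m = metrics_from_confusion(cm, tuple("abcdef"))
        assert m.accuracy == pytest.approx(1 / 6)

    def test_per_class_scores_match_sklearn(self, rng):
        labels = ["a", "b", "c", "d"]
        y_true = rng.choice(labels, size=300)
        y_pred = rng.choice(labels, size=300)
        from sklearn.metrics import confusion_matrix
        cm = confusion_matrix(y_true, y_pred, labels=labels)
        m = metrics_from_confusion(cm, labels)
        p, r, f, s = precision_recall_fscore_support(
            y_true, y_pred, labels=labels, zero_division=0)
        for i, lab in enumerate(labels):
            assert m.per_class[lab]["precision"] == pytest.approx(p[i])
            assert m.per_class[lab]["recall"] == pytest.approx(r[i])
            assert m.per_class[lab]["f1"] == pytest.approx(f[i])
            assert m.per_class[lab]["support"] == s[i]

    def test_row_sums_equal_support_and_trace_accuracy(self, rng):
        model = build_model(DEFAULT, seed=0)
        X = rng.normal(size=(30, 50))
        y = rng.choice(model.labels, size=30)
        m = evaluate(model, X, y)
        assert m.confusion.sum() == 30
        assert m.accuracy == pytest.approx(np.trace(m.confusion) / 30)
        for i, lab in enumerate(m.label_order):
            assert m.confusion[i].sum() == m.per_class[lab]["support"]

    def test_empty_test_set_rejected(self):
        model = build_model(DEFAULT, seed=0)
        with pytest.raises(ValueError):
            evaluate(model, np.zeros((0, 50)), [])


def test_save_load_round_trip(tmp_path, rng):
    model = build_model(DEFAULT, seed=5)
    X = rng.normal(size=(8, 50))
    before = model.predict_proba(X)
    model.save(tmp_path / "model")
    restored = CnnLstmClassifier.load(tmp_path / "model")
    assert np.array_equal(restored.predict_proba(X), before)
    assert restored.labels == model.labels
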