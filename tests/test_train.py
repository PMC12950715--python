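"""Training-loop and metric tests, with a brute-force F1 oracle."""

import numpy as np
import pytest

from tinyweednet.config import ArchConfig
from tinyweednet.data import DatasetBundle
from tinyweednet.network import assemble_network
from tinyweednet.train import (
    MetricsSummary,
    TrainConfig,
    evaluate,
    repeat_experiment,
    softmax_cross_entropy,
    train,
)

TINY = ArchConfig(stem_channels=4, input_side=32, dropout_p=0.0)


def brute_force_metrics(labels, preds, num_classes):
    """Accuracy and macro-F1 (percent) by explicit per-class counting."""
    acc = 100.0 * sum(int(p == l) for p, l in zip(preds, labels)) / len(labels)
    f1s = []
    for c in range(num_classes):
        tp = sum(1 for p, l in zip(preds, labels) if p == c and l == c)
        fp = sum(1 for p, l in zip(preds, labels) if p == c and l != c)
        fn = sum(1 for p, l in zip(preds, labels) if p != c and l == c)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
    return acc, 100.0 * sum(f1s) / num_classes


class _FixedPredictor:
    """Stands in for a network: returns one-hot logits for canned predictions."""

    def __init__(self, preds, num_classes):
        self.preds = np.asarray(preds)
        self.k = num_classes

    def forward(self, batch):
        out = np.zeros((len(batch), self.k), np.float32)
        taken, self.preds = self.preds[: len(batch)], self.preds[len(batch) :]
        out[np.arange(len(taken)), taken] = 1.0
        return out


def _bundle_from_labels(labels, num_classes, side=8):
    labels = np.asarray(labels)
    return DatasetBundle(
        images=np.zeros((len(labels), 3, side, side), np.float32),
        labels=labels,
        class_names=[f"c{i}" for i in range(num_classes)],
    )


class TestMetrics:
    @pytest.mark.parametrize(
        "labels, preds",
        [
            ([0, 1, 2, 2, 1, 0, 1, 2], [0, 1, 2, 1, 1, 0, 0, 2]),
            ([0, 0, 1, 1, 2, 2], [2, 2, 2, 2, 2, 2]),
            (list(range(9)) * 2, [0] * 18),
        ],
    )
    def test_matches_brute_force_oracle(self, labels, preds):
        k = max(max(labels), max(preds)) + 1
        summary = evaluate(_FixedPredictor(preds, k), _bundle_from_labels(labels, k))
        acc, f1 = brute_force_metrics(labels, preds, k)
        assert summary.accuracy_pct == pytest.approx(acc, abs=1e-9)
        assert summary.macro_f1_pct == pytest.approx(f1, abs=1e-9)

    def test_perfect_predictions(self):
        labels = [0, 1, 2, 0, 1, 2]
        summary = evaluate(_FixedPredictor(labels, 3), _bundle_from_labels(labels, 3))
        assert summary.accuracy_pct == 100.0
        assert summary.macro_f1_pct == 100.0
        assert np.trace(summary.confusion) == 6

    def test_single_class_collapse_on_balanced_set(self):
        labels = list(range(9)) * 3
        summary = evaluate(
            _FixedPredictor([4] * 27, 9), _bundle_from_labels(labels, 9)
        )
        assert summary.accuracy_pct == pytest.approx(100.0 / 9)

    def test_confusion_rows_sum_to_class_counts(self):
        labels = [0, 0, 1, 2, 2, 2]
        preds = [1, 0, 1, 0, 2, 2]
        summary = evaluate(_FixedPredictor(preds, 3), _bundle_from_labels(labels, 3))
        np.testing.assert_array_equal(summary.confusion.sum(axis=1), [2, 1, 3])


class TestCrossEntropy:
    def test_gradient_matches_probability_residual(self):
        logits = np.array([[2.0, 0.0, -1.0], [0.0, 0.0, 0.0]], np.float32)
        labels = np.array([0, 2])
        loss, grad = softmax_cross_entropy(logits, labels)
        probs = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        expected = probs.copy()
        expected[[0, 1], labels] -= 1.0
        np.testing.assert_allclose(grad, expected / 2, rtol=1e-6)
        assert loss == pytest.approx(
            -np.log(probs[0, 0]) / 2 - np.log(probs[1, 2]) / 2, rel=1e-5
        )


def _tiny_dataset(n=16, classes=4, side=32, seed=0):
    rng = np.random.default_rng(seed)
    labels = np.arange(n) % classes
    images = rng.random((n, 3, side, side), dtype=np.float32) * 0.25
    # plant a strong class-dependent color cue
    for i, c in enumerate(labels):
        images[i, c % 3] += 0.5 * (1 + c // 3) / 2
    return DatasetBundle(
        images=np.clip(images, 0, 1),
        labels=labels,
        class_names=[f"c{i}" for i in range(classes)],
    )


class TestTrainingLoop:
    def test_zero_learning_rate_leaves_weights_unchanged(self):
        net = assemble_network(ArchConfig(stem_channels=4, input_side=32), 1)
        before = {n: p.data.copy() for n, p in net.parameters()}
        data = _tiny_dataset()
        tc = TrainConfig(learning_rate=0.0, max_epochs=2, patience=1,
                         monitor="train_accuracy", seed=0)
        train(net, data, None, tc)
        for n, p in net.parameters():
            np.testing.assert_array_equal(p.data, before[n]), n

    def test_identical_seeds_identical_final_loss(self):
        data = _tiny_dataset()
        losses = []
        for _ in range(2):
            net = assemble_network(TINY, 5)
            tc = TrainConfig(learning_rate=0.01, max_epochs=3, patience=2,
                             monitor="train_accuracy", seed=4)
            hist = train(net, data, None, tc)
            losses.append(hist["loss"][-1])
        assert losses[0] == losses[1]

    def test_loss_decreases_when_overfitting_one_batch(self):
        data = _tiny_dataset(n=8)
        net = assemble_network(TINY, 2)
        tc = TrainConfig(learning_rate=0.05, momentum=0.9, batch_size=8,
                         max_epochs=8, patience=7, monitor="train_accuracy", seed=0)
        hist = train(net, data, None, tc)
        assert hist["loss"][-1] < 0.5 * hist["loss"][0]

    def test_divergence_raises(self):
        data = _tiny_dataset(n=8)
        net = assemble_network(TINY, 2)
        tc = TrainConfig(learning_rate=1e9, batch_size=8, max_epochs=5, patience=4,
                         monitor="train_accuracy", seed=0)
        with np.errstate(over="ignore", invalid="ignore"):
            with pytest.raises(FloatingPointError):
                train(net, data, None, tc)

    def test_monitor_requires_test_data(self):
        with pytest.raises(ValueError):
            train(assemble_network(TINY, 0), _tiny_dataset(), None,
                  TrainConfig(max_epochs=2, patience=1))


class TestRepeatExperiment:
    def test_identical_seeds_zero_sd(self):
        data = _tiny_dataset()
        tc = TrainConfig(learning_rate=0.01, max_epochs=2, patience=1,
                         monitor="train_accuracy", seed=3)
        summary = repeat_experiment(
            lambda s: assemble_network(TINY, s), data, data, tc, seeds=[7, 7]
        )
        assert summary.accuracy_sd == 0.0
        assert summary.macro_f1_sd == 0.0

    def test_mean_aggregates_individual_runs(self):
        data = _tiny_dataset()
        tc = TrainConfig(learning_rate=0.01, max_epochs=2, patience=1,
                         monitor="train_accuracy", seed=3)
        accs = []
        for s in (11, 12):
            net = assemble_network(TINY, s)
            train(net, data, data, TrainConfig(
                learning_rate=0.01, max_epochs=2, patience=1,
                monitor="train_accuracy", seed=s))
            accs.append(evaluate(net, data).accuracy_pct)
        summary = repeat_experiment(
            lambda s: assemble_network(TINY, s), data, data, tc, seeds=[11, 12]
        )
        assert summary.accuracy_pct == pytest.approx(np.mean(accs))

    def test_single_repeat_rejected(self):
        with pytest.raises(ValueError):
            repeat_experiment(
                lambda s: assemble_network(TINY, s),
                _tiny_dataset(),
                _tiny_dataset(),
                TrainConfig(max_epochs=2, patience=1),
                seeds=[1],
            )


class TestTrainConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"learning_rate": -1.0},
            {"batch_size": 0},
            {"momentum": 1.0},
            {"patience": 100, "max_epochs": 100},
            {"monitor": "val_loss"},
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            TrainConfig(**kwargs)
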