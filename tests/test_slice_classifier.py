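"""Linear probe on frozen features: class weights, training, thresholding."""

import numpy as np
import pytest

from cacvit.nn import Tensor
from cacvit.slice_classifier import (
    CalcifiedSliceClassifier,
    ClassifierConfig,
    LinearHead,
    classify_slices,
    compute_class_weights,
    train_classifier,
    weighted_cross_entropy,
)


class TestClassWeights:
    @pytest.mark.parametrize("pos_frac,expected", [
        (0.10, 9.0), (0.50, 1.0), (0.20, 4.0),
    ])
    def test_inverse_frequency_weights(self, pos_frac, expected):
        n = 1000
        labels = np.zeros(n, dtype=int)
        labels[: int(n * pos_frac)] = 1
        neg_w, pos_w = compute_class_weights(labels)
        assert neg_w == 1.0
        assert pos_w == pytest.approx(expected)

    def test_ratio_identity(self):
        rng = np.random.default_rng(0)
        labels = (rng.random(500) < 0.3).astype(int)
        neg_w, pos_w = compute_class_weights(labels)
        n_pos, n_neg = labels.sum(), (1 - labels).sum()
        assert pos_w / neg_w == pytest.approx(n_neg / n_pos)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_class_weights(np.ones(10, dtype=int))


class TestWeightedLoss:
    def test_unit_weights_reduce_to_plain_cross_entropy(self, rng):
        logits = rng.normal(size=(8, 2))
        y = rng.integers(0, 2, size=8)
        weighted = weighted_cross_entropy(Tensor(logits), y, (1.0, 1.0))
        z = logits - logits.max(axis=1, keepdims=True)
        logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
        plain = -logp[np.arange(8), y].mean()
        assert float(weighted.data) == pytest.approx(plain, rel=1e-9)


class TestTrainClassifier:
    def test_separable_features_reach_full_accuracy(self):
        rng = np.random.default_rng(0)
        X = np.concatenate([rng.normal(-3, 0.3, size=(40, 2)),
                            rng.normal(3, 0.3, size=(40, 2))])
        y = np.array([0] * 40 + [1] * 40)
        cfg = ClassifierConfig(lr=0.05, batch_size=16)
        head, _ = train_classifier(X, y, config=cfg, seed=0)
        pred, _ = classify_slices(head, X)
        assert (pred == y).mean() == 1.0

    def test_deterministic_under_seed(self, rng):
        X = rng.normal(size=(60, 4))
        y = rng.integers(0, 2, size=60)
        a, _ = train_classifier(X, y, seed=5)
        b, _ = train_classifier(X, y, seed=5)
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_early_stopping_halts_on_plateau(self):
        # features carry no signal at all -> validation F1 plateaus quickly
        rng = np.random.default_rng(1)
        X = np.zeros((40, 3))
        y = np.array([0, 1] * 20)
        cfg = ClassifierConfig(max_epochs=10, patience=3)
        _, history = train_classifier(X, y, config=cfg, seed=0)
        assert len(history["epoch"]) < cfg.max_epochs

    def test_best_epoch_weights_restored(self, rng):
        X = rng.normal(size=(50, 3))
        y = (X[:, 0] > 0).astype(int)
        head, history = train_classifier(X, y, seed=2)
        best = history["best_epoch"]
        assert history["val_f1"][best] == max(history["val_f1"])

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            train_classifier(rng.normal(size=(10, 3)), np.zeros(7, dtype=int))

    def test_single_class_labels_rejected(self, rng):
        with pytest.raises(ValueError):
            train_classifier(rng.normal(size=(10, 3)), np.ones(10, dtype=int))


class TestClassifySlices:
    def test_zero_head_gives_half_probability(self, rng):
        head = LinearHead(weights=np.zeros((4, 2)), bias=np.zeros(2))
        _, prob = classify_slices(head, rng.normal(size=(6, 4)))
        np.testing.assert_allclose(prob, 0.5)

    def test_threshold_boundary_semantics(self, rng):
        head = LinearHead(weights=np.zeros((4, 2)), bias=np.zeros(2))
        X = rng.normal(size=(6, 4))
        all_pos, _ = classify_slices(head, X, threshold=1e-12)
        assert all_pos.sum() == 6
        none_pos, _ = classify_slices(head, X, threshold=1.0 - 1e-12)
        assert none_pos.sum() == 0
        at_half, _ = classify_slices(head, X, threshold=0.5)
        assert at_half.sum() == 6  # p == threshold counts as positive

    def test_hand_softmax_arithmetic(self):
        W = np.array([[1.0, -1.0], [0.5, 0.5], [0.0, 2.0]])
        b = np.array([0.1, -0.1])
        head = LinearHead(weights=W, bias=b)
        X = np.array([[1.0, 2.0, 3.0]])
        logits = X @ W + b
        expected = np.exp(logits[0, 1]) / np.exp(logits[0]).sum()
        _, prob = classify_slices(head, X)
        assert prob[0] == pytest.approx(expected, rel=1e-12)

    def test_feature_dim_mismatch_rejected(self, rng):
        head = LinearHead(weights=np.zeros((4, 2)), bias=np.zeros(2))
        with pytest.raises(ValueError, match="dimension"):
            classify_slices(head, rng.normal(size=(3, 5)))


class TestDirectionRecovery:
    def test_learned_direction_aligns_with_truth(self):
        # two Gaussians separated along a known direction
        rng = np.random.default_rng(3)
        direction = np.array([1.0, 2.0, -1.0, 0.5])
        direction /= np.linalg.norm(direction)
        X = rng.normal(size=(300, 4))
        y = (X @ direction + rng.normal(0, 0.1, size=300) > 0).astype(int)
        cfg = ClassifierConfig(lr=0.05, batch_size=32)
        head, _ = train_classifier(X, y, config=cfg, seed=0)
        learned = head.weights[:, 1] - head.weights[:, 0]
        cos = learned @ direction / np.linalg.norm(learned)
        assert cos >= 0.9


class TestEstimatorApi:
    def test_fit_predict_and_params_round_trip(self, rng):
        X = np.concatenate([rng.normal(-2, 0.5, size=(30, 3)),
                            rng.normal(2, 0.5, size=(30, 3))])
        y = np.array([0] * 30 + [1] * 30)
        est = CalcifiedSliceClassifier(lr=0.05, seed=0)
        assert est.get_params()["lr"] == 0.05
        est.set_params(batch_size=16)
        est.fit(X, y)
        assert est.score(X, y) > 0.9
        proba = est.predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)

    def test_works_inside_sklearn_cross_validation(self, rng):
        from sklearn.model_selection import cross_val_score

        X = np.concatenate([rng.normal(-2, 0.5, size=(30, 3)),
                            rng.normal(2, 0.5, size=(30, 3))])
        y = np.array([0] * 30 + [1] * 30)
        scores = cross_val_score(CalcifiedSliceClassifier(lr=0.05, seed=0), X, y,
                                 cv=3)
        assert scores.mean() > 0.8
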