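"""Linear classification head on frozen self-supervised slice features.

A single fully connected layer maps each slice's embedding to two logits
(non-calcified / calcified).  Training minimizes class-weighted
cross-entropy — weights inversely proportional to class frequency, with the
negative class normalized to 1.0 (e.g. 10% positives gives weight 9.0 for
the calcified class) — with Adam (lr 1e-4, weight decay 1e-4, batch 64),
for at most 10 epochs with early stopping on validation F1 (patience 3);
the parameters from the best-F1 epoch are kept.  The backbone is never
touched: features are precomputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor
from .ssl_core import FeatureMatrix

__all__ = [
    "ClassifierConfig",
    "LinearHead",
    "compute_class_weights",
    "train_classifier",
    "classify_slices",
    "CalcifiedSliceClassifier",
]


@dataclass
class ClassifierConfig:
    lr: float = 1e-4
    weight_decay: float = 1e-4
    batch_size: int = 64
    max_epochs: int = 10
    patience: int = 3
    decision_threshold: float = 0.5

    def __post_init__(self):
        if not self.patience < self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")
        if not 0.0 < self.decision_threshold < 1.0:
            raise ValueError("decision threshold must lie in (0, 1)")


@dataclass
class LinearHead:
    """Weights (embed_dim, 2) and bias (2,) of the linear classifier."""

    weights: np.ndarray
    bias: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.bias = np.asarray(self.bias, dtype=np.float64)
        if self.weights.ndim != 2 or self.weights.shape[1] != 2 or self.bias.shape != (2,):
            raise ValueError("head must map embed_dim -> 2 logits")
        if not (np.all(np.isfinite(self.weights)) and np.all(np.isfinite(self.bias))):
            raise ValueError("head parameters must be finite")


def compute_class_weights(labels) -> tuple[float, float]:
    """(negative_weight, positive_weight) inversely proportional to frequency,
    normalized so the negative weight is 1.0."""
    y = np.asarray(labels).astype(int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute weights")
    return (1.0, n_neg / n_pos)


def _as_array(features) -> np.ndarray:
    if isinstance(features, FeatureMatrix):
        return features.values
    return np.asarray(features, dtype=np.float64)


def _positive_f1(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom > 0 else 0.0


def weighted_cross_entropy(logits: Tensor, labels: np.ndarray,
                           class_weights: tuple[float, float]) -> Tensor:
    """Class-weighted 2-class cross-entropy, normalized by the weight sum.

    With weights (1, 1) this reduces exactly to the unweighted mean
    cross-entropy.
    """
    y = np.asarray(labels).astype(int)
    w = np.asarray(class_weights, dtype=np.float64)[y]  # (N,)
    logp = logits.log_softmax(axis=-1)
    picked = logp[np.arange(len(y)), y]
    return -(Tensor(w) * picked).sum() * (1.0 / w.sum())


def train_classifier(features, labels, val_features=None, val_labels=None,
                     config: ClassifierConfig | None = None,
                     seed: int = 0) -> tuple[LinearHead, dict]:
    """Train the linear head on precomputed features.

    When no validation set is given, the training set doubles as the
    early-stopping set (desk-scale convenience; a held-out set is preferred).
    Returns the head restored from the best-validation-F1 epoch and a
    history dict with one entry per completed epoch.
    """
    cfg = config or ClassifierConfig()
    X = _as_array(features)
    y = np.asarray(labels).astype(int)
    if X.shape[0] != y.shape[0]:
        raise ValueError("feature rows and labels must align")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    if val_features is None:
        Xv, yv = X, y
    else:
        Xv = _as_array(val_features)
        yv = np.asarray(val_labels).astype(int)
        if Xv.shape[1] != X.shape[1]:
            raise ValueError("validation feature dimension mismatch")

    weights = compute_class_weights(y)
    rng = np.random.default_rng(seed)
    layer = nn.Linear(X.shape[1], 2, rng)
    opt = nn.Adam(layer.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)

    history = {"epoch": [], "train_loss": [], "val_f1": []}
    best = {"f1": -np.inf, "state": None, "epoch": -1}
    since_improve = 0
    Xf = X.astype(np.float32)
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(y))
        losses = []
        for b0 in range(0, len(y), cfg.batch_size):
            idx = order[b0:b0 + cfg.batch_size]
            logits = layer(Tensor(Xf[idx]))
            loss = weighted_cross_entropy(logits, y[idx], weights)
            layer.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        head = LinearHead(weights=layer.weight.data.copy().astype(np.float64),
                          bias=layer.bias.data.copy().astype(np.float64))
        pred, _ = classify_slices(head, Xv, threshold=cfg.decision_threshold)
        f1 = _positive_f1(yv, pred)
        history["epoch"].append(epoch)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_f1"].append(f1)
        if f1 > best["f1"]:
            best = {"f1": f1, "state": (head.weights.copy(), head.bias.copy()),
                    "epoch": epoch}
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= cfg.patience:
                break
    w, b = best["state"]
    history["best_epoch"] = best["epoch"]
    return LinearHead(weights=w, bias=b), history


def classify_slices(head: LinearHead, features, threshold: float = 0.5):
    """Per-slice binary labels and calcification probabilities.

    Probability is the softmax over the two logits; the label is 1 when
    p(calcified) >= threshold (boundary inclusive, so threshold 0 flags
    everything and threshold 1 flags nothing except certainty).
    """
    X = _as_array(features)
    if X.shape[1] != head.weights.shape[0]:
        raise ValueError(f"feature dimension {X.shape[1]} does not match head "
                         f"dimension {head.weights.shape[0]}")
    logits = X @ head.weights + head.bias
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    probs = e / e.sum(axis=1, keepdims=True)
    p1 = probs[:, 1]
    return (p1 >= threshold).astype(int), p1


from sklearn.base import BaseEstimator, ClassifierMixin


class CalcifiedSliceClassifier(ClassifierMixin, BaseEstimator):
    """Scikit-learn estimator for calcified-slice detection.

    Parameters mirror :class:`ClassifierConfig`; ``fit`` accepts an optional
    validation split for early stopping.  Fitted attributes: ``head_``,
    ``history_``, ``classes_``.
    """

    def __init__(self, lr: float = 1e-4, weight_decay: float = 1e-4,
                 batch_size: int = 64, max_epochs: int = 10, patience: int = 3,
                 decision_threshold: float = 0.5, seed: int = 0):
        self.lr = lr
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.decision_threshold = decision_threshold
        self.seed = seed

    def _config(self) -> ClassifierConfig:
        return ClassifierConfig(lr=self.lr, weight_decay=self.weight_decay,
                                batch_size=self.batch_size, max_epochs=self.max_epochs,
                                patience=self.patience,
                                decision_threshold=self.decision_threshold)

    def fit(self, X, y, X_val=None, y_val=None):
        self.head_, self.history_ = train_classifier(
            X, y, X_val, y_val, config=self._config(), seed=self.seed)
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X) -> np.ndarray:
        _, p1 = classify_slices(self.head_, X, threshold=self.decision_threshold)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        pred, _ = classify_slices(self.head_, X, threshold=self.decision_threshold)
        return pred
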