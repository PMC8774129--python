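"""Fixed-architecture feed-forward classifiers and tree baselines.

Two network shapes are used throughout the screening pipeline:

* **binary** (cancer vs normal, or one cancer type vs normal): a dense
  layer of 30 units, a hidden dense layer of 60 units, and a single
  sigmoid output;
* **multiclass** (simultaneous typing across C cancers): six hidden
  dense layers of 240 units each and a C-way softmax output.

Every dense layer except the output is followed by relu and dropout
(rate 0.1, inverted scaling at train time). Training is plain
mini-batch Adam (lr 0.001) with cross-entropy loss, batch size 20,
exactly 30 epochs, no early stopping; the training data are reshuffled
each epoch with the run seed. The implementation is pure numpy so that
a fixed seed reproduces weights, histories and predictions bit-for-bit.

Baselines (random forest, decision tree) come from scikit-learn behind
the same train/predict surface so evaluation code stays model-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from .expression_io import NORMAL_LABEL, ExpressionMatrix

__all__ = [
    "NNConfig",
    "TrainingHistory",
    "TrainedModel",
    "FeedForwardNet",
    "build_model",
    "train_model",
    "predict_scores",
    "build_baseline",
    "encode_labels",
]

BINARY_WIDTHS = (30, 60)
MULTICLASS_WIDTHS = (240,) * 6


@dataclass(frozen=True)
class NNConfig:
    """Architecture and training hyperparameters.

    ``layer_widths=None`` resolves to the task default: (30, 60) for
    binary screens, six layers of 240 for the multiclass typer. The
    ``log_transform`` flag applies log1p to inputs before training and
    prediction; it is off by default because the pipeline consumes raw
    TPM end to end.
    """

    task: str = "binary"
    layer_widths: tuple[int, ...] | None = None
    dropout_rate: float = 0.1
    activation: str = "relu"
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    epochs: int = 30
    batch_size: int = 20
    seed: int = 0
    log_transform: bool = False

    def __post_init__(self) -> None:
        if self.task not in ("binary", "multiclass"):
            raise ValueError("task must be 'binary' or 'multiclass'")
        if self.layer_widths is not None:
            widths = tuple(int(w) for w in self.layer_widths)
            if any(w < 1 for w in widths):
                raise ValueError("layer widths must be positive")
            object.__setattr__(self, "layer_widths", widths)
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.activation != "relu":
            raise ValueError("only relu activation is supported")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")

    @property
    def resolved_widths(self) -> tuple[int, ...]:
        if self.layer_widths is not None:
            return self.layer_widths
        return BINARY_WIDTHS if self.task == "binary" else MULTICLASS_WIDTHS


@dataclass(frozen=True)
class TrainingHistory:
    """Per-epoch traces, evaluated at epoch end without dropout."""

    train_loss: tuple[float, ...]
    train_accuracy: tuple[float, ...]
    val_loss: tuple[float, ...]
    val_accuracy: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.train_loss)
        if not (len(self.train_accuracy) == len(self.val_loss)
                == len(self.val_accuracy) == n):
            raise ValueError("history series must have equal length")
        for loss in (*self.train_loss, *self.val_loss):
            if loss < 0:
                raise ValueError("losses must be >= 0")
        for acc in (*self.train_accuracy, *self.val_accuracy):
            if not (0.0 <= acc <= 1.0):
                raise ValueError("accuracies must lie in [0, 1]")

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(1, self.n_epochs + 1),
                "train_loss": self.train_loss,
                "train_accuracy": self.train_accuracy,
                "val_loss": self.val_loss,
                "val_accuracy": self.val_accuracy,
            }
        )


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class FeedForwardNet:
    """Dense relu network with dropout, trained by mini-batch Adam.

    The output head is a single sigmoid unit (binary) or an
    ``n_classes``-way softmax (multiclass); the loss is the matching
    cross-entropy. All randomness (weight init, epoch shuffling, dropout
    masks) flows from ``config.seed``.
    """

    def __init__(self, n_features: int, n_classes: int, config: NNConfig):
        if n_features < 1:
            raise ValueError("n_features must be >= 1")
        if config.task == "binary" and n_classes != 2:
            raise ValueError("binary task requires n_classes == 2")
        if config.task == "multiclass" and n_classes < 2:
            raise ValueError("multiclass task requires n_classes >= 2")
        self.n_features = n_features
        self.n_classes = n_classes
        self.config = config
        self.n_out = 1 if config.task == "binary" else n_classes
        self._rng = np.random.default_rng(config.seed)
        widths = config.resolved_widths
        dims = [n_features, *widths, self.n_out]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            # He init for relu layers; the final (linear head) layer too —
            # scale only affects pre-sigmoid/softmax logits.
            w = self._rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
            self.weights.append(w)
            self.biases.append(np.zeros(fan_out))
        self._adam_t = 0
        self._adam_m = [np.zeros_like(w) for w in self.weights + self.biases]
        self._adam_v = [np.zeros_like(w) for w in self.weights + self.biases]

    # -- introspection ------------------------------------------------

    @property
    def n_parameters(self) -> int:
        return int(sum(w.size for w in self.weights) + sum(b.size for b in self.biases))

    # -- forward / loss ----------------------------------------------

    def _forward(self, X: np.ndarray, training: bool):
        """Returns (per-layer post-activation list, logits)."""
        acts = [X]
        h = X
        p_drop = self.config.dropout_rate
        masks = []
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ w + b
            if i < len(self.weights) - 1:
                h = np.maximum(z, 0.0)
                if training and p_drop > 0:
                    mask = (self._rng.random(h.shape) >= p_drop) / (1.0 - p_drop)
                    h = h * mask
                    masks.append(mask)
                else:
                    masks.append(None)
                acts.append(h)
            else:
                logits = z
        return acts, masks, logits

    def predict_logits(self, X: np.ndarray) -> np.ndarray:
        _, _, logits = self._forward(np.asarray(X, dtype=float), training=False)
        return logits

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        logits = self.predict_logits(X)
        if self.config.task == "binary":
            return expit(logits[:, 0])
        return _softmax(logits)

    def _loss_acc(self, X: np.ndarray, y: np.ndarray) -> tuple[float, float]:
        logits = self.predict_logits(X)
        if self.config.task == "binary":
            z = logits[:, 0]
            # stable BCE on logits
            loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
            acc = float(np.mean((z > 0).astype(float) == y))
        else:
            zs = logits - logits.max(axis=1, keepdims=True)
            logp = zs - np.log(np.exp(zs).sum(axis=1, keepdims=True))
            loss = float(-np.mean(logp[np.arange(len(y)), y]))
            acc = float(np.mean(np.argmax(logits, axis=1) == y))
        return loss, acc

    # -- training ------------------------------------------------------

    def _adam_step(self, grads: list[np.ndarray]) -> None:
        cfg = self.config
        self._adam_t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        params = self.weights + self.biases
        for i, (p, g) in enumerate(zip(params, grads)):
            self._adam_m[i] = b1 * self._adam_m[i] + (1 - b1) * g
            self._adam_v[i] = b2 * self._adam_v[i] + (1 - b2) * g * g
            m_hat = self._adam_m[i] / (1 - b1**self._adam_t)
            v_hat = self._adam_v[i] / (1 - b2**self._adam_t)
            p -= cfg.learning_rate * m_hat / (np.sqrt(v_hat) + eps)

    def _batch_grads(self, X: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
        acts, masks, logits = self._forward(X, training=True)
        B = X.shape[0]
        if self.config.task == "binary":
            delta = (expit(logits[:, 0]) - y)[:, None] / B
        else:
            probs = _softmax(logits)
            probs[np.arange(B), y] -= 1.0
            delta = probs / B
        grads_w: list[np.ndarray] = [None] * len(self.weights)
        grads_b: list[np.ndarray] = [None] * len(self.biases)
        for i in range(len(self.weights) - 1, -1, -1):
            grads_w[i] = acts[i].T @ delta
            grads_b[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.weights[i].T
                if masks[i - 1] is not None:
                    delta = delta * masks[i - 1]
                delta = delta * (acts[i] > 0)
        return grads_w + grads_b

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        X_val: np.ndarray,
        y_val: np.ndarray,
    ) -> TrainingHistory:
        """Exactly ``config.epochs`` passes in ``config.batch_size`` batches."""
        cfg = self.config
        X = np.asarray(X, dtype=float)
        X_val = np.asarray(X_val, dtype=float)
        y = np.asarray(y)
        y_val = np.asarray(y_val)
        tl, ta, vl, va = [], [], [], []
        n = len(X)
        for epoch in range(cfg.epochs):
            order = self._rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                batch = order[start:start + cfg.batch_size]
                self._adam_step(self._batch_grads(X[batch], y[batch]))
            loss, acc = self._loss_acc(X, y)
            loss_v, acc_v = self._loss_acc(X_val, y_val)
            if not (np.isfinite(loss) and np.isfinite(loss_v)):
                raise FloatingPointError(
                    f"loss became non-finite at epoch {epoch + 1}; raw TPM "
                    "scales vary over orders of magnitude — consider "
                    "NNConfig(log_transform=True)"
                )
            tl.append(loss)
            ta.append(acc)
            vl.append(loss_v)
            va.append(acc_v)
        return TrainingHistory(tuple(tl), tuple(ta), tuple(vl), tuple(va))


@dataclass(frozen=True)
class TrainedModel:
    """Fitted predictor plus the feature/class order it expects."""

    net: FeedForwardNet
    feature_ids: tuple[str, ...]
    classes: tuple[str, ...]
    config: NNConfig


def build_model(n_features: int, n_classes: int, config: NNConfig) -> FeedForwardNet:
    """Instantiate the (untrained) network for the given problem size."""
    return FeedForwardNet(n_features, n_classes, config)


def encode_labels(labels: Sequence[str], task: str) -> tuple[np.ndarray, tuple[str, ...]]:
    """Encode string labels for training.

    Binary: positive class = anything other than ``"normal"`` (cancer of
    any type); returns 0/1 floats and the class order (negative,
    positive). Multiclass: classes sorted alphabetically, integer codes.
    """
    labels = np.asarray(labels)
    if task == "binary":
        y = (labels != NORMAL_LABEL).astype(float)
        if len(np.unique(y)) < 2:
            raise ValueError("binary task requires both normal and cancer samples")
        positive = sorted(set(labels[labels != NORMAL_LABEL]))
        pos_name = positive[0] if len(positive) == 1 else "cancer"
        return y, (NORMAL_LABEL, pos_name)
    classes = tuple(sorted(set(labels)))
    if len(classes) < 2:
        raise ValueError("multiclass task requires >= 2 classes")
    lookup = {c: i for i, c in enumerate(classes)}
    return np.array([lookup[c] for c in labels]), classes


def _as_frame(X, feature_ids=None) -> pd.DataFrame:
    if isinstance(X, ExpressionMatrix):
        return X.data
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(X.shape[1])]
    return pd.DataFrame(X, columns=list(feature_ids))


def train_model(
    model: FeedForwardNet,
    train_X,
    train_y: Sequence[str],
    val_X,
    val_y: Sequence[str],
    config: NNConfig | None = None,
) -> tuple[TrainedModel, TrainingHistory]:
    """Train ``model`` on labelled expression data.

    ``train_X``/``val_X`` may be :class:`ExpressionMatrix`, DataFrame or
    array; labels are class strings (``"normal"`` marks controls).
    """
    config = config or model.config
    Xtr = _as_frame(train_X)
    Xva = _as_frame(val_X)
    if list(Xtr.columns) != list(Xva.columns):
        Xva = Xva.loc[:, Xtr.columns]
    ytr, classes = encode_labels(train_y, config.task)
    yva, _ = encode_labels(val_y, config.task)
    if config.task == "multiclass":
        # validation labels must map into the training class order
        lookup = {c: i for i, c in enumerate(classes)}
        unseen = set(np.asarray(val_y)) - set(classes)
        if unseen:
            raise ValueError(f"validation labels unseen in training: {sorted(unseen)}")
        yva = np.array([lookup[c] for c in np.asarray(val_y)])
    Atr, Ava = Xtr.to_numpy(dtype=float), Xva.to_numpy(dtype=float)
    if config.log_transform:
        Atr, Ava = np.log1p(Atr), np.log1p(Ava)
    history = model.fit(Atr, ytr, Ava, yva)
    trained = TrainedModel(model, tuple(Xtr.columns), classes, config)
    return trained, history


def predict_scores(model: TrainedModel, X) -> np.ndarray:
    """Predict probabilities, aligning columns by feature identifier.

    Binary: one probability of cancer per sample. Multiclass: one row of
    class probabilities (summing to 1) per sample, column order
    ``model.classes``.
    """
    df = _as_frame(X, model.feature_ids)
    missing = [f for f in model.feature_ids if f not in df.columns]
    if missing:
        raise KeyError(f"input is missing model features: {missing[:5]}")
    A = df.loc[:, list(model.feature_ids)].to_numpy(dtype=float)
    if model.config.log_transform:
        A = np.log1p(A)
    return model.net.predict_proba(A)


def build_baseline(kind: str, seed: int = 0, **kwargs):
    """A conventional-model baseline with the scikit-learn fit/predict
    surface: ``random_forest`` or ``decision_tree`` at library-default
    hyperparameters, seeded for reproducibility."""
    if kind == "random_forest":
        return RandomForestClassifier(random_state=seed, **kwargs)
    if kind == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **kwargs)
    raise ValueError(f"unknown baseline kind {kind!r}; "
                     "choose 'random_forest' or 'decision_tree'")
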