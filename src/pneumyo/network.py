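"""Lightweight CNN-LSTM activity classifier with embedded-budget accounting.

The network maps a standardized 500 ms pressure window (50 samples at
100 Hz, one channel) to a probability vector over the six locomotion
modes:

    conv1d(48 filters, kernel 4, valid, ReLU) -> maxpool(2)
    -> LSTM(24, full sequence) -> dropout(0.3)
    -> LSTM(12, final state)  -> dropout(0.3)
    -> dense(6, softmax)

Training uses Adam and categorical cross-entropy.  Besides building,
training and evaluating the model, the module provides closed-form
accounting for embedded deployment: trainable-parameter count, flat weight
size in bytes, and a multiply-accumulate (MACC) estimate under a stated
counting convention.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion_matrix

from . import _nn
from .pipeline import DatasetSplit
from .synth import MODES

__all__ = [
    "ArchitectureSpec",
    "TrainingConfig",
    "Metrics",
    "CnnLstmClassifier",
    "count_trainable_params",
    "build_model",
    "train",
    "evaluate",
    "flat_size_bytes",
    "macc_estimate",
    "MACC_CONVENTION",
]


@dataclass(frozen=True)
class ArchitectureSpec:
    """Hyperparameters of the classifier network."""

    window_length: int = 50
    input_channels: int = 1
    conv_filters: int = 48
    conv_kernel: int = 4
    pool_size: int = 2
    lstm_units: tuple[int, int] = (24, 12)
    dropout_rate: float = 0.3
    num_classes: int = 6

    def __post_init__(self) -> None:
        for name in ("window_length", "input_channels", "conv_filters",
                     "conv_kernel", "pool_size", "num_classes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.pooled_length < 1:
            raise ValueError("pooled sequence length must be >= 1")

    @property
    def conv_out_length(self) -> int:
        return self.window_length - self.conv_kernel + 1

    @property
    def pooled_length(self) -> int:
        return self.conv_out_length // self.pool_size


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization settings: Adam step size, epochs, batch size, seed."""

    learning_rate: float = 1e-3
    epochs: int = 300
    batch_size: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class Metrics:
    """Confusion matrix and the per-class scores derived from it."""

    confusion: np.ndarray
    label_order: tuple[str, ...]
    accuracy: float
    per_class: dict[str, dict[str, float]]

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_class": self.per_class,
            "confusion": self.confusion.astype(int).tolist(),
            "label_order": list(self.label_order),
        }


def count_trainable_params(spec: ArchitectureSpec) -> int:
    """Closed-form trainable-parameter count.

    conv: filters*(kernel*channels) + filters; each LSTM:
    4*units*(input_dim + units + 1); dense: in*classes + classes.
    Independent of the window length.
    """
    total = spec.conv_filters * (spec.conv_kernel * spec.input_channels) + spec.conv_filters
    in_dim = spec.conv_filters
    for units in spec.lstm_units:
        total += 4 * units * (in_dim + units + 1)
        in_dim = units
    total += in_dim * spec.num_classes + spec.num_classes
    return total


def flat_size_bytes(spec: ArchitectureSpec, bytes_per_weight: int = 4) -> int:
    """Flat weight-storage size: parameter count times bytes per weight."""
    if bytes_per_weight <= 0:
        raise ValueError("bytes_per_weight must be > 0")
    return count_trainable_params(spec) * bytes_per_weight


MACC_CONVENTION = (
    "conv: out_len*filters*kernel*channels; "
    "lstm: steps*4*units*(input_dim+units); dense: in*out; "
    "biases, activations and pooling excluded"
)


def macc_estimate(spec: ArchitectureSpec) -> int:
    """Multiply-accumulate count for one inference under :data:`MACC_CONVENTION`.

    Indicative only; vendor toolchains use their own (undocumented)
    conventions and will not match exactly.
    """
    total = (spec.conv_out_length * spec.conv_filters
             * spec.conv_kernel * spec.input_channels)
    steps = spec.pooled_length
    in_dim = spec.conv_filters
    for units in spec.lstm_units:
        total += steps * 4 * units * (in_dim + units)
        in_dim = units
    total += in_dim * spec.num_classes
    return total


class CnnLstmClassifier:
    """Trainable CNN-LSTM over fixed-length pressure windows.

    Parameters are plain numpy arrays in ``self.params``; the class-to-index
    mapping is fixed (alphabetical over the label vocabulary) and persisted
    with the model.
    """

    def __init__(self, spec: ArchitectureSpec, seed: int = 0,
                 labels: Sequence[str] = MODES):
        self.spec = spec
        self.labels = tuple(sorted(labels))
        if len(self.labels) != spec.num_classes:
            raise ValueError(
                f"{len(self.labels)} labels for {spec.num_classes} classes")
        self.params = self._init_params(np.random.default_rng(seed))
        self.history: dict[str, list[float]] = {}

    # ------------------------------------------------------------ parameters
    def _init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        s = self.spec
        p: dict[str, np.ndarray] = {}
        K, C, F = s.conv_kernel, s.input_channels, s.conv_filters
        p["conv_W"] = _nn.glorot_uniform(rng, (K, C, F), K * C, F)
        p["conv_b"] = np.zeros(F)
        in_dim = F
        for li, H in enumerate(s.lstm_units, start=1):
            p[f"lstm{li}_W"] = _nn.glorot_uniform(rng, (in_dim, 4 * H), in_dim, 4 * H)
            p[f"lstm{li}_U"] = _nn.orthogonal(rng, H, 4 * H)
            b = np.zeros(4 * H)
            b[H : 2 * H] = 1.0  # forget-gate bias
            p[f"lstm{li}_b"] = b
            in_dim = H
        p["dense_W"] = _nn.glorot_uniform(rng, (in_dim, s.num_classes),
                                          in_dim, s.num_classes)
        p["dense_b"] = np.zeros(s.num_classes)
        return p

    def param_count(self) -> int:
        """Total size of the actual weight arrays (the framework-side count)."""
        return int(sum(v.size for v in self.params.values()))

    # --------------------------------------------------------------- forward
    def _forward(self, X: np.ndarray, train: bool = False,
                 rng: Optional[np.random.Generator] = None):
        s, p = self.spec, self.params
        x = X.reshape(X.shape[0], s.window_length, s.input_channels)
        z, conv_cache = _nn.conv1d_forward(x, p["conv_W"], p["conv_b"])
        relu_mask = z > 0
        a = z * relu_mask
        pooled, pool_cache = _nn.maxpool1d_forward(a, s.pool_size)
        h1, l1_cache = _nn.lstm_forward(pooled, p["lstm1_W"], p["lstm1_U"], p["lstm1_b"])
        caches = {"conv": conv_cache, "relu": relu_mask, "pool": pool_cache,
                  "l1": l1_cache, "drop1": None, "drop2": None}
        if train and s.dropout_rate > 0:
            m1 = (rng.random(h1.shape) >= s.dropout_rate) / (1.0 - s.dropout_rate)
            h1 = h1 * m1
            caches["drop1"] = m1
        h2, l2_cache = _nn.lstm_forward(h1, p["lstm2_W"], p["lstm2_U"], p["lstm2_b"])
        caches["l2"] = l2_cache
        last = h2[:, -1, :]
        if train and s.dropout_rate > 0:
            m2 = (rng.random(last.shape) >= s.dropout_rate) / (1.0 - s.dropout_rate)
            last = last * m2
            caches["drop2"] = m2
        logits, dense_cache = _nn.dense_forward(last, p["dense_W"], p["dense_b"])
        caches["dense"] = dense_cache
        probs = _nn.softmax(logits)
        return probs, caches

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class probabilities, shape (n, num_classes); rows sum to 1."""
        probs, _ = self._forward(np.asarray(X, dtype=float), train=False)
        return probs

    def predict(self, X: np.ndarray) -> np.ndarray:
        idx = self.predict_proba(X).argmax(axis=1)
        return np.array([self.labels[i] for i in idx], dtype=object)

    # -------------------------------------------------------------- backward
    def _backward(self, probs: np.ndarray, y_onehot: np.ndarray, caches):
        s = self.spec
        B = probs.shape[0]
        grads: dict[str, np.ndarray] = {}
        dlogits = (probs - y_onehot) / B
        x_dense = caches["dense"]
        grads["dense_W"] = x_dense.T @ dlogits
        grads["dense_b"] = dlogits.sum(axis=0)
        dlast = dlogits @ self.params["dense_W"].T
        if caches["drop2"] is not None:
            dlast = dlast * caches["drop2"]
        T2 = s.pooled_length
        dh2 = np.zeros((B, T2, s.lstm_units[1]))
        dh2[:, -1, :] = dlast
        dh1, dW2, dU2, db2 = _nn.lstm_backward(dh2, caches["l2"])
        grads["lstm2_W"], grads["lstm2_U"], grads["lstm2_b"] = dW2, dU2, db2
        if caches["drop1"] is not None:
            dh1 = dh1 * caches["drop1"]
        dpooled, dW1, dU1, db1 = _nn.lstm_backward(dh1, caches["l1"])
        grads["lstm1_W"], grads["lstm1_U"], grads["lstm1_b"] = dW1, dU1, db1
        da = _nn.maxpool1d_backward(dpooled, caches["pool"])
        dz = da * caches["relu"]
        _, dWc, dbc = _nn.conv1d_backward(dz, caches["conv"])
        grads["conv_W"], grads["conv_b"] = dWc, dbc
        return grads

    # ------------------------------------------------------------------ fit
    def _encode(self, y: Sequence[str]) -> np.ndarray:
        index = {lab: i for i, lab in enumerate(self.labels)}
        try:
            idx = np.array([index[lab] for lab in y])
        except KeyError as err:
            raise ValueError(f"label {err.args[0]!r} outside vocabulary "
                             f"{self.labels}") from None
        onehot = np.zeros((len(idx), self.spec.num_classes))
        onehot[np.arange(len(idx)), idx] = 1.0
        return onehot

    def fit(self, X: np.ndarray, y: Sequence[str], cfg: TrainingConfig) -> dict:
        """Mini-batch Adam on categorical cross-entropy; returns the history.

        All randomness (shuffling, dropout masks) derives from ``cfg.seed``.
        """
        X = np.asarray(X, dtype=float)
        onehot = self._encode(y)
        rng = np.random.default_rng(cfg.seed)
        opt = _nn.Adam(lr=cfg.learning_rate)
        n = X.shape[0]
        loss_hist: list[float] = []
        acc_hist: list[float] = []
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            losses = []
            correct = 0
            for start in range(0, n, cfg.batch_size):
                sel = order[start : start + cfg.batch_size]
                probs, caches = self._forward(X[sel], train=True, rng=rng)
                eps = 1e-12
                losses.append(float(
                    -np.mean(np.sum(onehot[sel] * np.log(probs + eps), axis=1))))
                correct += int((probs.argmax(1) == onehot[sel].argmax(1)).sum())
                grads = self._backward(probs, onehot[sel], caches)
                opt.step(self.params, grads)
            loss_hist.append(float(np.mean(losses)))
            acc_hist.append(correct / n)
        self.history = {"loss": loss_hist, "accuracy": acc_hist}
        return self.history

    # ----------------------------------------------------------- persistence
    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez(path / "weights.npz", **self.params)
        meta = {"spec": asdict(self.spec), "labels": list(self.labels)}
        (path / "model.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path) -> "CnnLstmClassifier":
        path = Path(path)
        meta = json.loads((path / "model.json").read_text())
        spec_d = meta["spec"]
        spec_d["lstm_units"] = tuple(spec_d["lstm_units"])
        model = cls(ArchitectureSpec(**spec_d), labels=meta["labels"])
        with np.load(path / "weights.npz") as z:
            model.params = {k: z[k].copy() for k in z.files}
        return model


def build_model(spec: ArchitectureSpec, seed: int = 0,
                labels: Sequence[str] = MODES) -> CnnLstmClassifier:
    """Instantiate an untrained classifier for ``spec``."""
    return CnnLstmClassifier(spec, seed=seed, labels=labels)


def train(model: CnnLstmClassifier, split: DatasetSplit,
          cfg: TrainingConfig) -> tuple[CnnLstmClassifier, dict]:
    """Train on the split's training portion; returns the model and history."""
    if split.train_X.size == 0:
        raise ValueError("empty training set")
    history = model.fit(split.train_X, split.train_y, cfg)
    return model, history


def metrics_from_confusion(confusion: np.ndarray,
                           label_order: Sequence[str]) -> Metrics:
    """Accuracy and per-class precision/recall/F1 computed from the matrix."""
    cm = np.asarray(confusion, dtype=float)
    total = cm.sum()
    accuracy = float(np.trace(cm) / total) if total else 0.0
    per_class: dict[str, dict[str, float]] = {}
    for i, lab in enumerate(label_order):
        tp = cm[i, i]
        fp = cm[:, i].sum() - tp
        fn = cm[i, :].sum() - tp
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = (2 * precision * recall / (precision + recall)
              if precision + recall else 0.0)
        per_class[lab] = {"precision": float(precision), "recall": float(recall),
                          "f1": float(f1), "support": int(cm[i, :].sum())}
    return Metrics(confusion=np.asarray(confusion, dtype=int),
                   label_order=tuple(label_order),
                   accuracy=accuracy, per_class=per_class)


def evaluate(model: CnnLstmClassifier, X: np.ndarray,
             y: Sequence[str]) -> Metrics:
    """Confusion matrix plus accuracy and per-class precision/recall/F1."""
    y = np.asarray(y, dtype=object)
    if y.size == 0:
        raise ValueError("empty test set")
    pred = model.predict(np.asarray(X, dtype=float))
    cm = _sk_confusion_matrix(y, pred, labels=list(model.labels))
    return metrics_from_confusion(cm, model.labels)
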