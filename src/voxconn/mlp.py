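"""Feed-forward classifier for Source-Target vectors, with Nadam training.

Architecture: input -> dense(64, sigmoid) -> dropout -> dense(32, relu) ->
dropout -> dense(32, relu) -> dropout -> output head, where the head is a
3-way softmax trained with categorical cross-entropy (multi-class task) or
a single sigmoid trained with binary cross-entropy (binary task).

Training uses the Nesterov-accelerated Adam (Nadam) update with a
1/(1 + decay * t) learning-rate schedule, mini-batch shuffling, inverted
dropout, and Glorot-uniform initialization.  Everything is seeded, so a
fixed config reproduces weights, history and predictions bit for bit.  The
network is small enough that a plain numpy implementation trains the
reference problems in seconds on one CPU core.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support, roc_curve

from voxconn.datasets import DatasetSplit, SourceTargetDataset
from voxconn.errors import ConfigError

_ACTIVATIONS = {"sigmoid", "relu"}


@dataclass(frozen=True)
class MLPConfig:
    """Architecture and training regime of the classifier."""

    input_dim: int
    task: str = "multiclass"  # or "binary"
    hidden_widths: tuple[int, ...] = (64, 32, 32)
    hidden_activations: tuple[str, ...] = ("sigmoid", "relu", "relu")
    dropout_rates: tuple[float, ...] = (0.3, 0.2, 0.2)
    n_classes: int = 3
    learning_rate: float = 0.002
    decay: float = 0.004
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-7
    epochs: int = 200
    batch_size: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_dim < 1:
            raise ConfigError("input_dim must be positive")
        if self.task not in {"multiclass", "binary"}:
            raise ConfigError(f"unknown task {self.task!r}")
        if self.task == "multiclass" and self.n_classes < 2:
            raise ConfigError("multiclass needs >= 2 classes")
        if not (
            len(self.hidden_widths)
            == len(self.hidden_activations)
            == len(self.dropout_rates)
        ):
            raise ConfigError("hidden widths/activations/dropouts must align")
        if any(w < 1 for w in self.hidden_widths):
            raise ConfigError("hidden widths must be positive")
        if any(a not in _ACTIVATIONS for a in self.hidden_activations):
            raise ConfigError(f"activations must be in {_ACTIVATIONS}")
        if any(not 0 <= r < 1 for r in self.dropout_rates):
            raise ConfigError("dropout rates must lie in [0, 1)")
        if self.epochs < 0 or self.batch_size < 1:
            raise ConfigError("epochs must be >= 0, batch_size >= 1")

    @property
    def output_dim(self) -> int:
        return self.n_classes if self.task == "multiclass" else 1

    @classmethod
    def multiclass_default(cls, input_dim: int, seed: int = 0, **kw) -> "MLPConfig":
        """200 epochs, batch size 6, softmax head, categorical cross-entropy."""
        kw.setdefault("epochs", 200)
        kw.setdefault("batch_size", 6)
        return cls(input_dim=input_dim, task="multiclass", seed=seed, **kw)

    @classmethod
    def binary_default(cls, input_dim: int, seed: int = 0, **kw) -> "MLPConfig":
        """100 epochs, batch size 32, sigmoid head, binary cross-entropy."""
        kw.setdefault("epochs", 100)
        kw.setdefault("batch_size", 32)
        return cls(input_dim=input_dim, task="binary", n_classes=2, seed=seed, **kw)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class MLP:
    """The network: a list of dense layers with explicit forward/backward."""

    def __init__(self, config: MLPConfig):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
        widths = [config.input_dim, *config.hidden_widths, config.output_dim]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(widths[:-1], widths[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            self.weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    @property
    def n_parameters(self) -> int:
        """Trainable parameters: sum of (fan_in + 1) * fan_out over layers."""
        return sum(w.size + b.size for w, b in zip(self.weights, self.biases))

    # -- forward -----------------------------------------------------------

    def _forward(
        self,
        x: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, list]:
        cfg = self.config
        cache = []
        a = x
        n_hidden = len(cfg.hidden_widths)
        for layer in range(n_hidden):
            z = a @ self.weights[layer] + self.biases[layer]
            act = cfg.hidden_activations[layer]
            h = _sigmoid(z) if act == "sigmoid" else np.maximum(z, 0.0)
            mask = None
            rate = cfg.dropout_rates[layer]
            if training and rate > 0:
                if rng is None:
                    raise ConfigError("training forward pass needs an rng")
                mask = (rng.random(h.shape) >= rate) / (1.0 - rate)
                h = h * mask
            cache.append((a, z, h, mask))
            a = h
        logits = a @ self.weights[-1] + self.biases[-1]
        cache.append((a, logits, None, None))
        return logits, cache

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities: (n, k) softmax or (n,) sigmoid scores."""
        logits, _ = self._forward(np.asarray(x, dtype=float))
        if self.config.task == "multiclass":
            return _softmax(logits)
        return _sigmoid(logits[:, 0])

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Hard labels: argmax (multiclass) or score > 0.5 (binary)."""
        p = self.predict_proba(x)
        if self.config.task == "multiclass":
            return p.argmax(axis=1)
        return (p > 0.5).astype(int)

    # -- backward ----------------------------------------------------------

    def _backward(
        self, cache: list, dlogits: np.ndarray
    ) -> tuple[list[np.ndarray], list[np.ndarray]]:
        cfg = self.config
        n_hidden = len(cfg.hidden_widths)
        grads_w = [None] * len(self.weights)
        grads_b = [None] * len(self.biases)
        a_last = cache[-1][0]
        grads_w[-1] = a_last.T @ dlogits
        grads_b[-1] = dlogits.sum(axis=0)
        da = dlogits @ self.weights[-1].T
        for layer in range(n_hidden - 1, -1, -1):
            a_prev, z, h, mask = cache[layer]
            if mask is not None:
                da = da * mask
            if cfg.hidden_activations[layer] == "sigmoid":
                # h already includes the dropout mask; recompute plain sigmoid
                s = _sigmoid(z)
                dz = da * s * (1.0 - s)
            else:
                dz = da * (z > 0)
            grads_w[layer] = a_prev.T @ dz
            grads_b[layer] = dz.sum(axis=0)
            da = dz @ self.weights[layer].T
        return grads_w, grads_b


def _loss_and_grad(
    model: MLP, logits: np.ndarray, y: np.ndarray
) -> tuple[float, np.ndarray]:
    n = len(y)
    if model.config.task == "multiclass":
        p = _softmax(logits)
        onehot = np.eye(model.config.n_classes)[y]
        loss = float(-(onehot * np.log(np.clip(p, 1e-12, None))).sum() / n)
        return loss, (p - onehot) / n
    p = _sigmoid(logits[:, 0])
    eps = 1e-12
    loss = float(
        -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
    )
    return loss, ((p - y) / n)[:, None]


class _Nadam:
    """Nesterov-accelerated Adam with 1/(1 + decay*t) learning-rate decay."""

    def __init__(self, params: Sequence[np.ndarray], config: MLPConfig):
        self.cfg = config
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: Sequence[np.ndarray], grads: Sequence[np.ndarray]) -> None:
        cfg = self.cfg
        lr = cfg.learning_rate / (1.0 + cfg.decay * self.t)
        self.t += 1
        t = self.t
        b1, b2 = cfg.beta1, cfg.beta2
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_bar = (
                b1 * self.m[i] / (1 - b1 ** (t + 1))
                + (1 - b1) * g / (1 - b1**t)
            )
            v_hat = self.v[i] / (1 - b2**t)
            p -= lr * m_bar / (np.sqrt(v_hat) + cfg.epsilon)


def _check_labels(y: np.ndarray, config: MLPConfig) -> None:
    if config.task == "multiclass":
        if y.min() < 0 or y.max() >= config.n_classes:
            raise ConfigError(
                f"labels outside 0..{config.n_classes - 1} for multiclass head"
            )
    elif not np.isin(y, [0, 1]).all():
        raise ConfigError("binary head needs labels in {0, 1}")


def train(
    model: MLP, split: DatasetSplit, config: MLPConfig | None = None
) -> pd.DataFrame:
    """Train for exactly config.epochs epochs; returns the per-epoch history.

    The validation part is only monitored, never used for updates or
    stopping.  History columns: epoch, train_loss, train_accuracy, val_loss,
    val_accuracy.  Deterministic given the config seed.
    """
    cfg = config or model.config
    x, y = split.train.features.astype(float), split.train.labels
    if x.shape[1] != cfg.input_dim:
        raise ConfigError(
            f"features have {x.shape[1]} dims, model expects {cfg.input_dim}"
        )
    _check_labels(y, cfg)
    has_val = len(split.validation) > 0
    if has_val:
        xv = split.validation.features.astype(float)
        yv = split.validation.labels
        _check_labels(yv, cfg)

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 13]))
    params = model.weights + model.biases
    opt = _Nadam(params, cfg)
    history = []
    n = len(y)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            logits, cache = model._forward(x[idx], training=True, rng=rng)
            _, dlogits = _loss_and_grad(model, logits, y[idx])
            gw, gb = model._backward(cache, dlogits)
            opt.step(params, gw + gb)
        tr_loss, tr_acc = _dataset_metrics(model, x, y)
        if has_val:
            va_loss, va_acc = _dataset_metrics(model, xv, yv)
        else:
            va_loss = va_acc = np.nan
        history.append(
            {
                "epoch": epoch + 1,
                "train_loss": tr_loss,
                "train_accuracy": tr_acc,
                "val_loss": va_loss,
                "val_accuracy": va_acc,
            }
        )
    return pd.DataFrame(
        history,
        columns=["epoch", "train_loss", "train_accuracy", "val_loss", "val_accuracy"],
    )


def _dataset_metrics(model: MLP, x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    logits, _ = model._forward(x)
    loss, _ = _loss_and_grad(model, logits, y)
    if model.config.task == "multiclass":
        pred = logits.argmax(axis=1)
    else:
        pred = (_sigmoid(logits[:, 0]) > 0.5).astype(int)
    return loss, float((pred == y).mean())


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvalReport:
    """Test-set quality report: confusion matrix, per-class metrics, ROC."""

    confusion: np.ndarray  # counts, rows = true class, cols = predicted
    confusion_pct: np.ndarray  # row-normalized percentages
    precision: np.ndarray  # per class; NaN where undefined
    recall: np.ndarray
    f1: np.ndarray
    accuracy: float
    auc: float | None = None
    roc: tuple[np.ndarray, np.ndarray] | None = None  # (fpr, tpr)
    history: pd.DataFrame | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        def clean(a: np.ndarray) -> list:
            return [None if np.isnan(v) else float(v) for v in a]

        out = {
            "confusion_matrix": self.confusion.tolist(),
            "confusion_matrix_pct": np.round(self.confusion_pct, 2).tolist(),
            "precision": clean(self.precision),
            "recall": clean(self.recall),
            "f1": clean(self.f1),
            "accuracy": float(self.accuracy),
        }
        if self.auc is not None:
            out["auc"] = float(self.auc)
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    def format_table(self, class_names: Sequence[str] | None = None) -> str:
        """Human-readable per-class metric table."""
        k = len(self.precision)
        names = class_names or [f"class {i}" for i in range(k)]
        lines = [f"{'':>18} {'Recall':>8} {'Precision':>10} {'F1':>8}"]
        for i in range(k):
            def fmt(v: float) -> str:
                return "   n/a" if np.isnan(v) else f"{100 * v:5.0f}%"
            lines.append(
                f"{names[i]:>18} {fmt(self.recall[i]):>8} "
                f"{fmt(self.precision[i]):>10} {fmt(self.f1[i]):>8}"
            )
        lines.append(f"{'Accuracy':>18} {100 * self.accuracy:7.1f}%")
        if self.auc is not None:
            lines.append(f"{'AUC':>18} {self.auc:8.3f}")
        return "\n".join(lines)


def evaluate(
    model: MLP,
    test: SourceTargetDataset,
    history: pd.DataFrame | None = None,
) -> EvalReport:
    """Score the model on a held-out set.

    Confusion-matrix rows are the true classes, columns the predicted ones;
    per-class precision/recall/F1 are NaN (undefined) for classes absent
    from the test set.  The binary task additionally reports the ROC curve
    over the sigmoid score and its trapezoidal AUC.
    """
    if len(test) == 0:
        raise ConfigError("cannot evaluate on an empty test set")
    y = test.labels
    cfg = model.config
    k = cfg.n_classes
    pred = model.predict(test.features.astype(float))
    cm = _sk_confusion(y, pred, labels=list(range(k)))
    row_sums = cm.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        cm_pct = 100.0 * cm / row_sums
    precision, recall, f1, _ = precision_recall_fscore_support(
        y, pred, labels=list(range(k)), zero_division=np.nan
    )
    # a class with no true members has undefined recall/F1 regardless of
    # predictions; force NaN rather than 0
    absent = ~np.isin(np.arange(k), np.unique(y))
    recall = np.where(absent, np.nan, recall)
    f1 = np.where(absent, np.nan, f1)
    accuracy = float(np.trace(cm) / cm.sum())
    auc_val = None
    roc_pair = None
    if cfg.task == "binary" and len(np.unique(y)) == 2:
        scores = model.predict_proba(test.features.astype(float))
        fpr, tpr, _ = roc_curve(y, scores)
        auc_val = float(_trapezoid_auc(fpr, tpr))
        roc_pair = (fpr, tpr)
    return EvalReport(
        cm, cm_pct, precision, recall, f1, accuracy, auc_val, roc_pair, history
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def save_model(model: MLP, path: str | Path) -> None:
    """Single-file snapshot: config JSON plus all weight arrays."""
    cfg = model.config
    cfg_json = json.dumps(
        {
            "input_dim": cfg.input_dim,
            "task": cfg.task,
            "hidden_widths": list(cfg.hidden_widths),
            "hidden_activations": list(cfg.hidden_activations),
            "dropout_rates": list(cfg.dropout_rates),
            "n_classes": cfg.n_classes,
            "learning_rate": cfg.learning_rate,
            "decay": cfg.decay,
            "beta1": cfg.beta1,
            "beta2": cfg.beta2,
            "epsilon": cfg.epsilon,
            "epochs": cfg.epochs,
            "batch_size": cfg.batch_size,
            "seed": cfg.seed,
        }
    )
    arrays = {f"w{i}": w for i, w in enumerate(model.weights)}
    arrays.update({f"b{i}": b for i, b in enumerate(model.biases)})
    np.savez(path, config=np.array(cfg_json), **arrays)


def load_model(path: str | Path) -> MLP:
    with np.load(path, allow_pickle=False) as data:
        cfg_dict = json.loads(str(data["config"]))
        cfg_dict["hidden_widths"] = tuple(cfg_dict["hidden_widths"])
        cfg_dict["hidden_activations"] = tuple(cfg_dict["hidden_activations"])
        cfg_dict["dropout_rates"] = tuple(cfg_dict["dropout_rates"])
        model = MLP(MLPConfig(**cfg_dict))
        model.weights = [data[f"w{i}"] for i in range(len(model.weights))]
        model.biases = [data[f"b{i}"] for i in range(len(model.biases))]
    return model
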