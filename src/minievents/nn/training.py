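"""Training, evaluation and transfer learning for the window classifier."""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from .layers import DTYPE, sigmoid
from .network import EventClassifier
from .optim import AdamAMSGrad

__all__ = ["TrainingSet", "TrainConfig", "TLConfig", "train_classifier",
           "evaluate_classifier", "apply_transfer_learning"]

_SCALE_TOL = 1e-6


@dataclass
class TrainingSet:
    """Fixed-length, min-max scaled windows with binary labels."""

    windows: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.windows = np.asarray(self.windows, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.windows.ndim != 2:
            raise ValueError("windows must be a 2-D (n, window_len) array")
        if self.labels.shape != (self.windows.shape[0],):
            raise ValueError("labels must be one per window")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary (0/1)")
        self.labels = self.labels.astype(np.int8)
        if self.windows.size and (self.windows.min() < -_SCALE_TOL
                                  or self.windows.max() > 1 + _SCALE_TOL):
            raise ValueError("windows must be min-max scaled to [0, 1]")

    def __len__(self) -> int:
        return self.windows.shape[0]

    @property
    def window_len(self) -> int:
        return self.windows.shape[1]

    @property
    def positive_fraction(self) -> float:
        return float(self.labels.mean()) if len(self) else 0.0

    def subset(self, idx: np.ndarray) -> "TrainingSet":
        return TrainingSet(self.windows[idx], self.labels[idx])


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 2e-5
    batch_size: int = 128
    max_epochs: int = 100
    early_stop_patience: int = 8
    split_fraction: float = 0.75
    monitor: str = "val_loss"  # or "val_accuracy"
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must lie in (0, 1)")
        if self.early_stop_patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


@dataclass(frozen=True)
class TLConfig:
    """Hyperparameters for transfer learning with frozen conv blocks."""

    learning_rate: float = 2e-8
    early_stop_patience: int = 15
    batch_size: int = 32
    dropout_rate: float = 0.5
    max_epochs: int = 100
    split_fraction: float = 0.75
    monitor: str = "val_loss"
    freeze_conv: bool = True
    seed: int = 0


def _bce_loss_and_grad(logits: np.ndarray, labels: np.ndarray):
    """Binary cross-entropy from logits; gradient w.r.t. logits."""
    y = labels.astype(np.float64)
    z = logits.astype(np.float64)
    # log(1 + e^z) - y*z, computed stably; NaN propagates to the caller's
    # finiteness check rather than warning here
    with np.errstate(invalid="ignore"):
        loss = np.mean(np.logaddexp(0.0, z) - y * z)
    grad = (sigmoid(z.astype(DTYPE)).astype(np.float64) - y) / y.size
    return loss, grad.astype(DTYPE)


def _eval_loss_acc(model: EventClassifier, windows, labels, batch_size=128):
    scores = model.predict(windows, batch_size=batch_size)
    eps = 1e-12
    y = labels.astype(np.float64)
    loss = -np.mean(y * np.log(scores + eps)
                    + (1 - y) * np.log(1 - scores + eps))
    acc = float(np.mean((scores > 0.5) == (y > 0.5)))
    return float(loss), acc, scores


def _fit(model: EventClassifier, data: TrainingSet, *, learning_rate: float,
         batch_size: int, max_epochs: int, patience: int,
         split_fraction: float, monitor: str, seed: int,
         verbose: bool = False) -> EventClassifier:
    if len(data) == 0:
        raise ValueError("training set is empty")
    if data.window_len != model.window_len:
        raise ValueError(
            f"training windows have length {data.window_len} but the model "
            f"expects {model.window_len}; resample the windows first")
    if len(np.unique(data.labels)) < 2:
        raise ValueError("training data must contain both classes")

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(data))
    n_train = int(round(split_fraction * len(data)))
    train_idx, val_idx = order[:n_train], order[n_train:]
    if len(np.unique(data.labels[train_idx])) < 2 or val_idx.size == 0:
        raise ValueError("train/validation split left a single-class subset")

    Xtr = np.ascontiguousarray(data.windows[train_idx], dtype=DTYPE)
    ytr = data.labels[train_idx]
    Xval = np.ascontiguousarray(data.windows[val_idx], dtype=DTYPE)
    yval = data.labels[val_idx]

    opt = AdamAMSGrad(model.parameters(), learning_rate)
    history = {"loss": [], "accuracy": [], "val_loss": [], "val_accuracy": []}
    best_metric = np.inf if monitor == "val_loss" else -np.inf
    best_weights = model.get_weights()
    wait = 0

    for epoch in range(max_epochs):
        perm = rng.permutation(len(Xtr))
        ep_loss = 0.0
        ep_correct = 0
        for start in range(0, len(Xtr), batch_size):
            idx = perm[start:start + batch_size]
            xb, yb = Xtr[idx], ytr[idx]
            model.zero_grad()
            logits = model.forward_logits(xb, training=True, rng=rng)
            loss, dlogits = _bce_loss_and_grad(logits, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; reduce the "
                    f"learning rate or check the input scaling")
            model.backward(dlogits)
            opt.step()
            ep_loss += loss * len(idx)
            ep_correct += int(np.sum((logits > 0) == (yb > 0.5)))

        val_loss, val_acc, _ = _eval_loss_acc(model, Xval, yval)
        history["loss"].append(ep_loss / len(Xtr))
        history["accuracy"].append(ep_correct / len(Xtr))
        history["val_loss"].append(val_loss)
        history["val_accuracy"].append(val_acc)
        if verbose:
            print(f"epoch {epoch + 1}: loss={history['loss'][-1]:.4f} "
                  f"acc={history['accuracy'][-1]:.4f} val_loss={val_loss:.4f} "
                  f"val_acc={val_acc:.4f}")

        metric = val_loss if monitor == "val_loss" else val_acc
        improved = (metric < best_metric if monitor == "val_loss"
                    else metric > best_metric)
        if improved:
            best_metric = metric
            best_weights = model.get_weights()
            wait = 0
        else:
            wait += 1
            if wait >= patience:
                break

    model.set_weights(best_weights)
    model.history = history
    return model


def train_classifier(model: EventClassifier, data: TrainingSet,
                     cfg: TrainConfig | None = None,
                     verbose: bool = False) -> EventClassifier:
    """Train with Adam/AMSGrad, early stopping and best-epoch restore."""
    cfg = cfg or TrainConfig()
    model = _fit(model, data, learning_rate=cfg.learning_rate,
                 batch_size=cfg.batch_size, max_epochs=cfg.max_epochs,
                 patience=cfg.early_stop_patience,
                 split_fraction=cfg.split_fraction, monitor=cfg.monitor,
                 seed=cfg.seed, verbose=verbose)
    model.provenance["train_config"] = cfg.__dict__ | {}
    return model


def evaluate_classifier(model: EventClassifier, data: TrainingSet) -> dict:
    """Accuracy at the 0.5 cutoff plus ROC curve and its area."""
    if len(np.unique(data.labels)) < 2:
        raise ValueError("AUC is undefined for a single-class evaluation set")
    loss, acc, scores = _eval_loss_acc(
        model, np.ascontiguousarray(data.windows, dtype=DTYPE), data.labels)
    from sklearn.metrics import roc_curve, roc_auc_score
    fpr, tpr, thresholds = roc_curve(data.labels, scores)
    return {
        "loss": loss,
        "accuracy": acc,
        "auc": float(roc_auc_score(data.labels, scores)),
        "roc_points": np.column_stack([fpr, tpr]),
        "thresholds": thresholds,
    }


def apply_transfer_learning(base: EventClassifier, data: TrainingSet,
                            cfg: TLConfig | None = None,
                            verbose: bool = False) -> EventClassifier:
    """Retrain LSTM and dense layers on new data; conv blocks stay frozen.

    The returned model is a copy; ``base`` is left untouched.  Input
    windows must already be resampled to the base model's window length.
    """
    cfg = cfg or TLConfig()
    if data.window_len != base.window_len:
        raise ValueError(
            f"transfer-learning windows have length {data.window_len}; "
            f"resample them to {base.window_len} to match the base model")
    model = copy.deepcopy(base)
    if cfg.freeze_conv:
        model.freeze_conv_blocks()
    model.head_dropout.rate = cfg.dropout_rate
    model = _fit(model, data, learning_rate=cfg.learning_rate,
                 batch_size=cfg.batch_size, max_epochs=cfg.max_epochs,
                 patience=cfg.early_stop_patience,
                 split_fraction=cfg.split_fraction, monitor=cfg.monitor,
                 seed=cfg.seed, verbose=verbose)
    model.provenance["transfer_config"] = cfg.__dict__ | {}
    return model
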