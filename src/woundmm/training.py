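"""Mini-batch training loop with the two checkpoint callbacks.

Protocol defaults: 250 epochs, batch size 25, learning rate 0.001, Adam;
sparse categorical cross-entropy for multi-class heads and binary
cross-entropy for sigmoid heads. Two checkpoints are tracked throughout:
the epoch with the best validation accuracy, and the epoch with the best
combination of training and validation accuracy (their mean by default,
configurable to their minimum).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .architectures import ModelHandle
from .nn import Adam, binary_crossentropy, get_weights, set_weights, sparse_categorical_crossentropy


class TrainingDiverged(RuntimeError):
    """Loss became non-finite; training aborted with diagnostics."""


@dataclass(frozen=True)
class TrainingConfig:
    epochs: int = 250
    batch_size: int = 25
    learning_rate: float = 0.001
    seed: int = 0
    combined_policy: str = "mean"  # mean | min of (train_acc, val_acc)

    def __post_init__(self) -> None:
        if self.combined_policy not in ("mean", "min"):
            raise ValueError(f"unknown combined policy {self.combined_policy!r}")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")

    def combined_score(self, train_acc: float, val_acc: float) -> float:
        if self.combined_policy == "mean":
            return (train_acc + val_acc) / 2.0
        return min(train_acc, val_acc)


@dataclass
class Checkpoint:
    """Weight snapshot at the argmax epoch of one checkpoint policy."""

    policy: str
    epoch: int  # 1-based
    score: float
    train_acc: float
    val_acc: float
    weights: list[np.ndarray] = field(repr=False, default_factory=list)

    def restore(self, handle: ModelHandle) -> None:
        set_weights(handle.net, self.weights)


@dataclass
class TrainResult:
    history: list[dict]
    best_val: Checkpoint
    best_combined: Checkpoint

    @property
    def epochs(self) -> int:
        return len(self.history)


def _slice(x, idx):
    if isinstance(x, (tuple, list)):
        return tuple(xi[idx] for xi in x)
    return x[idx]


def _n_samples(x) -> int:
    return len(x[0]) if isinstance(x, (tuple, list)) else len(x)


def _predictions(handle: ModelHandle, probs: np.ndarray) -> np.ndarray:
    if handle.n_classes == 2:
        return (probs.reshape(-1) >= 0.5).astype(int)
    return np.argmax(probs, axis=1)


def evaluate(handle: ModelHandle, x, y, batch_size: int = 64) -> tuple[float, float]:
    """(loss, accuracy) of a model on a labelled set, without dropout."""
    loss_fn = (
        sparse_categorical_crossentropy if handle.loss_kind == "categorical" else binary_crossentropy
    )
    n = _n_samples(x)
    total_loss = 0.0
    correct = 0
    for start in range(0, n, batch_size):
        xb = _slice(x, slice(start, start + batch_size))
        yb = y[start : start + batch_size]
        probs = handle.net.forward(xb, training=False)
        loss, _ = loss_fn(probs, yb)
        total_loss += loss * len(yb)
        correct += int((_predictions(handle, probs) == yb).sum())
    return total_loss / n, correct / n


def train(
    handle: ModelHandle,
    x_train,
    y_train,
    x_val,
    y_val,
    config: TrainingConfig | None = None,
) -> TrainResult:
    """Train in place; returns the per-epoch history and both checkpoints.

    Training accuracy is accumulated over the epoch's mini-batches (with
    dropout active, as trained); validation metrics come from a clean full
    pass at the end of each epoch.
    """
    config = config or TrainingConfig()
    n = _n_samples(x_train)
    if n == 0:
        raise ValueError("empty training set")
    y_train = np.asarray(y_train)
    y_val = np.asarray(y_val)
    loss_fn = (
        sparse_categorical_crossentropy if handle.loss_kind == "categorical" else binary_crossentropy
    )
    opt = Adam(learning_rate=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    trainable = list(handle.net.iter_trainable())
    history: list[dict] = []
    best_val: Checkpoint | None = None
    best_combined: Checkpoint | None = None

    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        ep_loss = 0.0
        ep_correct = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = _slice(x_train, idx)
            yb = y_train[idx]
            probs = handle.net.forward(xb, training=True)
            loss, dlogits = loss_fn(probs, yb)
            if not np.isfinite(loss):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch} (batch starting {start})"
                )
            handle.net.backward(dlogits, skip_activation=True)
            opt.step(trainable)
            ep_loss += loss * len(yb)
            ep_correct += int((_predictions(handle, probs) == yb).sum())
        train_loss = ep_loss / n
        train_acc = ep_correct / n
        val_loss, val_acc = evaluate(handle, x_val, y_val)
        history.append(
            {
                "epoch": epoch,
                "train_loss": train_loss,
                "train_acc": train_acc,
                "val_loss": val_loss,
                "val_acc": val_acc,
            }
        )
        if best_val is None or val_acc > best_val.score:
            best_val = Checkpoint(
                "best_val_acc", epoch, val_acc, train_acc, val_acc, get_weights(handle.net)
            )
        combined = config.combined_score(train_acc, val_acc)
        if best_combined is None or combined > best_combined.score:
            best_combined = Checkpoint(
                "best_combined_acc", epoch, combined, train_acc, val_acc, get_weights(handle.net)
            )
    return TrainResult(history, best_val, best_combined)
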