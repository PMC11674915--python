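"""Training protocol: Adam, plateau learning-rate decay, best-checkpoint
retention, and evaluation.

The protocol mirrors the study setup: categorical cross-entropy minimized by
Adam, a fixed number of epochs with no data augmentation, learning rate
reduced by a factor of 0.3 (floored at 1e-6) when the validation loss
stagnates, and retention of the weights from the epoch with the highest
validation accuracy (ties resolved toward the earliest epoch).  The initial
learning rate (1e-3) and the plateau patience (5 epochs) are conventional
defaults, recorded here because the protocol description leaves them open.

Runs are reproducible: batch order is a pure function of the configured seed
and the epoch number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .data import DatasetIndex
from .engine import Adam, Model, softmax_cross_entropy
from .metrics import ConfusionMatrix, MetricsReport, confusion, report

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "preprocess",
    "load_arrays",
    "plateau_update",
    "train",
    "evaluate",
    "plot_curves",
]


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 128
    optimizer: str = "adam"
    initial_lr: float = 1e-3
    plateau_factor: float = 0.3
    plateau_min_lr: float = 1e-6
    plateau_patience: int = 5
    plateau_monitor: str = "val_loss"
    checkpoint_monitor: str = "val_accuracy"
    loss: str = "categorical_cross_entropy"
    augmentation: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.loss != "categorical_cross_entropy":
            raise ValueError("only categorical cross-entropy is supported")
        if not (0 < self.plateau_factor < 1):
            raise ValueError("plateau_factor must lie in (0, 1)")
        if self.plateau_min_lr > self.initial_lr:
            raise ValueError("plateau_min_lr must not exceed initial_lr")
        if self.augmentation:
            raise ValueError("data augmentation is deliberately unsupported")


@dataclass
class TrainHistory:
    """Per-epoch records of one training run."""

    rows: list[dict] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows,
            columns=[
                "epoch",
                "train_loss",
                "train_accuracy",
                "val_loss",
                "val_accuracy",
                "learning_rate",
            ],
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrainHistory":
        return cls(rows=pd.read_csv(path).to_dict("records"))

    def best_epoch(self) -> dict:
        """Row with maximal validation accuracy; ties toward the earliest."""
        return max(self.rows, key=lambda r: (r["val_accuracy"], -r["epoch"]))


def preprocess(image, size: tuple[int, int] = (224, 224)) -> np.ndarray:
    """Decode to a (3, H, W) float32 tensor in [0, 1].

    Grayscale inputs are replicated to three channels, RGB passed through;
    everything is bilinearly resized and scaled by 1/255.
    """
    if isinstance(image, (str, Path)):
        with Image.open(image) as im:
            return preprocess(im.copy(), size)
    if isinstance(image, np.ndarray):
        image = Image.fromarray(image)
    if image.mode not in ("L", "RGB"):
        image = image.convert("RGB" if len(image.getbands()) >= 3 else "L")
    if image.size != (size[1], size[0]):
        image = image.resize((size[1], size[0]), Image.BILINEAR)
    arr = np.asarray(image, dtype=np.float32) / 255.0
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=0)
    else:
        arr = arr.transpose(2, 0, 1)
    return arr


def load_arrays(index: DatasetIndex, size=(224, 224)) -> tuple[np.ndarray, np.ndarray]:
    """Preprocess every image of an index into one (N, 3, H, W) batch."""
    if len(index) == 0:
        raise ValueError("empty dataset index")
    x = np.stack([preprocess(e.path, size) for e in index.entries])
    return x, index.labels()


def plateau_update(current_lr: float, stale_epochs: int, config: TrainConfig) -> float:
    """New learning rate after ``stale_epochs`` without val-loss improvement.

    Returns ``max(current_lr * factor, min_lr)`` once staleness reaches the
    patience, else the unchanged rate.  A reduction implies the caller resets
    its staleness counter (the training loop does).
    """
    if stale_epochs >= config.plateau_patience:
        return max(current_lr * config.plateau_factor, config.plateau_min_lr)
    return current_lr


def _forward_in_batches(model: Model, x: np.ndarray, batch: int = 32) -> np.ndarray:
    return np.concatenate(
        [model.forward(x[i : i + batch]) for i in range(0, len(x), batch)]
    )


def _loss_acc(probs: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    p_true = np.clip(probs[np.arange(len(labels)), labels], 1e-12, None)
    return float(-np.log(p_true).mean()), float((probs.argmax(1) == labels).mean())


def train(
    model: Model,
    partitions: tuple[DatasetIndex, DatasetIndex, DatasetIndex] | tuple[DatasetIndex, DatasetIndex],
    config: TrainConfig | None = None,
) -> tuple[Model, TrainHistory]:
    """Fit ``model`` on the train split, checkpointing on validation accuracy.

    ``partitions`` is (train, val) or (train, val, test); the test split is
    ignored here.  Returns the model restored to its best-validation-accuracy
    weights plus the full history (one row per epoch).
    """
    config = config or TrainConfig()
    train_idx, val_idx = partitions[0], partitions[1]
    if len(train_idx) == 0 or len(val_idx) == 0:
        raise ValueError("train and validation partitions must be nonempty")
    size = (model.in_shape.height, model.in_shape.width)
    x_train, y_train = load_arrays(train_idx, size)
    x_val, y_val = load_arrays(val_idx, size)

    opt = Adam(model.params(), lr=config.initial_lr)
    history = TrainHistory()
    best_acc, best_weights, stale, best_val_loss = -1.0, model.get_weights(), 0, np.inf

    for epoch in range(1, config.epochs + 1):
        lr_in_effect = opt.lr
        order = np.random.default_rng([config.seed, epoch]).permutation(len(x_train))
        losses, correct = [], 0
        for start in range(0, len(order), config.batch_size):
            sel = order[start : start + config.batch_size]
            xb, yb = x_train[sel], y_train[sel]
            probs = model.forward(xb, training=True)
            loss, dlogits = softmax_cross_entropy(probs, yb)
            model.backward(dlogits)
            opt.step(model.grads())
            losses.append(loss * len(sel))
            correct += int((probs.argmax(1) == yb).sum())
        train_loss = float(np.sum(losses) / len(order))
        train_acc = correct / len(order)

        val_probs = _forward_in_batches(model, x_val)
        val_loss, val_acc = _loss_acc(val_probs, y_val)

        if val_acc > best_acc:
            best_acc, best_weights = val_acc, model.get_weights()
        if val_loss < best_val_loss - 1e-12:
            best_val_loss, stale = val_loss, 0
        else:
            stale += 1
            new_lr = plateau_update(opt.lr, stale, config)
            if new_lr != opt.lr:
                opt.lr = new_lr
                stale = 0

        history.rows.append(
            {
                "epoch": epoch,
                "train_loss": train_loss,
                "train_accuracy": train_acc,
                "val_loss": val_loss,
                "val_accuracy": val_acc,
                "learning_rate": lr_in_effect,
            }
        )

    model.set_weights(best_weights)
    return model, history


def evaluate(
    model: Model, test: DatasetIndex, batch: int = 32
) -> tuple[ConfusionMatrix, MetricsReport]:
    """Argmax predictions on a held-out split, aggregated into metrics."""
    if len(test) == 0:
        raise ValueError("empty test partition")
    size = (model.in_shape.height, model.in_shape.width)
    x, y = load_arrays(test, size)
    probs = _forward_in_batches(model, x, batch)
    pred = probs.argmax(axis=1)  # argmax ties resolve to the lowest index
    cm = confusion(y, pred, k=len(test.class_names), class_names=test.class_names)
    return cm, report(cm)


def plot_curves(history: TrainHistory, out) -> None:
    """Training/validation accuracy and loss convergence curves."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = history.to_dataframe()
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    axes[0].plot(df["epoch"], df["train_accuracy"], label="train")
    axes[0].plot(df["epoch"], df["val_accuracy"], label="validation")
    axes[0].set_xlabel("epoch")
    axes[0].set_ylabel("accuracy")
    axes[0].legend()
    axes[1].plot(df["epoch"], df["train_loss"], label="train")
    axes[1].plot(df["epoch"], df["val_loss"], label="validation")
    axes[1].set_xlabel("epoch")
    axes[1].set_ylabel("loss")
    axes[1].legend()
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)
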