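"""SGD-with-momentum training with early stopping and curve logging.

The protocol mirrors the published training setup: mini-batches of 16, SGD
with momentum 0.9, learning rate 1e-4, up to 300 epochs from scratch, early
stopping on validation loss.  The update rule is the classical heavy-ball
form ``v <- momentum * v - lr * grad; w <- w + v``; with momentum 0 it
reduces to plain gradient descent.  All randomness (shuffling, dropout) fans
out from the config seed, so a run is reproducible end to end.

Desk-scale benchmark runs use a larger learning rate and an optional
validation-accuracy stop (:attr:`TrainConfig.val_accuracy_goal`); both are
plain config fields, the paper-protocol defaults are unchanged.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import engine as E
from .datasets import DatasetManifest
from .network import NetworkInstance
from .preprocess import DiatomCrop

__all__ = ["TrainConfig", "TrainLog", "train", "train_arrays", "resolve_split_arrays"]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    momentum: float = 0.9
    batch_size: int = 16
    max_epochs: int = 300
    patience: int = 10  # early stopping, monitored on validation loss
    min_delta: float = 0.0
    seed: int = 0
    shuffle_each_epoch: bool = True
    val_accuracy_goal: Optional[float] = None  # optional additional stop rule
    eval_batch_size: int = 32

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not (0.0 <= self.momentum < 1.0):
            raise ValueError("momentum must be in [0, 1)")
        if self.batch_size < 1 or self.patience < 1 or self.max_epochs < 1:
            raise ValueError("batch_size, patience and max_epochs must be >= 1")


@dataclass
class TrainLog:
    """Per-epoch loss/accuracy curves plus stopping bookkeeping."""

    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0

    def to_rows(self) -> list[dict]:
        return [
            {
                "epoch": i + 1,
                "train_loss": self.train_loss[i],
                "train_accuracy": self.train_accuracy[i],
                "val_loss": self.val_loss[i],
                "val_accuracy": self.val_accuracy[i],
            }
            for i in range(len(self.train_loss))
        ]

    def write_csv(self, path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            fh.write("epoch,train_loss,train_accuracy,val_loss,val_accuracy\n")
            for r in self.to_rows():
                fh.write(
                    f"{r['epoch']},{r['train_loss']:.6f},{r['train_accuracy']:.6f},"
                    f"{r['val_loss']:.6f},{r['val_accuracy']:.6f}\n"
                )
            fh.write(f"# stopped_epoch={self.stopped_epoch} best_epoch={self.best_epoch}\n")


def resolve_split_arrays(
    manifest: DatasetManifest,
    split: str,
    crops: Optional[Sequence[DiatomCrop] | dict[str, np.ndarray]] = None,
    crop_dir=None,
    labels: Optional[tuple[str, ...]] = None,
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Materialize one split as ``(X, y, labels)``.

    Crops come either from an in-memory crop sequence/dict or from image
    files referenced by the manifest paths (relative to ``crop_dir``).
    Labels are the sorted species of the whole manifest unless given.
    """
    if labels is None:
        labels = tuple(sorted({r.species for r in manifest.rows}))
    label_to_idx = {s: i for i, s in enumerate(labels)}
    lookup: dict[str, np.ndarray] = {}
    if crops is not None:
        if isinstance(crops, dict):
            lookup = dict(crops)
        else:
            lookup = {c.crop_id: c.pixels for c in crops}
    rows = [r for r in manifest.rows if r.split == split]
    if not rows:
        raise ValueError(f"manifest has no crops in split {split!r}")
    xs, ys = [], []
    for r in rows:
        if r.species not in label_to_idx:
            raise ValueError(f"crop {r.crop_id}: species {r.species!r} not in label set")
        if r.crop_id in lookup:
            px = lookup[r.crop_id]
        elif r.path != "-":
            import imageio.v3 as iio

            p = Path(r.path)
            if crop_dir is not None and not p.is_absolute():
                p = Path(crop_dir) / p
            px = np.asarray(iio.imread(p), dtype=np.float32) / 255.0
        else:
            raise ValueError(f"crop {r.crop_id} has no pixels and no file path")
        xs.append(np.asarray(px, dtype=np.float32))
        ys.append(label_to_idx[r.species])
    return np.stack(xs), np.asarray(ys, dtype=np.int64), labels


def _eval_pass(
    net: NetworkInstance, X: np.ndarray, y: np.ndarray, batch: int
) -> tuple[float, float]:
    """Mean cross-entropy and accuracy in inference mode."""
    losses, correct = 0.0, 0
    n = len(X)
    for i in range(0, n, batch):
        xb = net._to_input_batch(X[i : i + batch])
        logits = net.forward_logits(xb, training=False)
        p = E.softmax_probs(logits)
        eps = np.finfo(p.dtype).tiny
        losses += float(-np.log(p[np.arange(len(xb)), y[i : i + batch]] + eps).sum())
        correct += int((p.argmax(axis=1) == y[i : i + batch]).sum())
    return losses / n, correct / n


def train_arrays(
    net: NetworkInstance,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    config: TrainConfig,
) -> tuple[NetworkInstance, TrainLog]:
    """Core training loop on materialized arrays; returns best-epoch weights."""
    if len(X_train) == 0 or len(X_val) == 0:
        raise ValueError("training and validation splits must be nonempty")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    net.reseed_dropout(config.seed + 1)

    params = net.parameter_store()
    velocity = {k: np.zeros_like(v) for k, v in params.items()}
    log = TrainLog()
    best_loss = math.inf
    best_params = net.copy_parameters()
    since_best = 0

    n = len(X_train)
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n) if config.shuffle_each_epoch else np.arange(n)
        ep_loss, ep_correct = 0.0, 0
        for b0 in range(0, n, config.batch_size):
            idx = order[b0 : b0 + config.batch_size]
            xb = net._to_input_batch(X_train[idx])
            yb = y_train[idx]
            net.zero_grads()
            logits = net.forward_logits(xb, training=True)
            loss, dlogits = E.softmax_cross_entropy(logits, yb)
            if not math.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, batch {b0 // config.batch_size}"
                )
            net.backward_logits(dlogits)
            for label, obj in net.layers:
                for name, g in obj.grads.items():
                    key = f"{label}/{name}"
                    v = velocity[key]
                    v *= config.momentum
                    v -= config.learning_rate * g
                    params[key] += v
            ep_loss += loss * len(idx)
            ep_correct += int((logits.argmax(axis=1) == yb).sum())
        val_loss, val_acc = _eval_pass(net, X_val, y_val, config.eval_batch_size)
        log.train_loss.append(ep_loss / n)
        log.train_accuracy.append(ep_correct / n)
        log.val_loss.append(val_loss)
        log.val_accuracy.append(val_acc)
        log.stopped_epoch = epoch

        if best_loss - val_loss > config.min_delta:
            best_loss = val_loss
            log.best_epoch = epoch
            best_params = net.copy_parameters()
            since_best = 0
        else:
            since_best += 1
        if config.val_accuracy_goal is not None and val_acc >= config.val_accuracy_goal:
            break
        if since_best >= config.patience:
            break

    net.load_parameters(best_params)
    return net, log


def train(
    net: NetworkInstance,
    manifest: DatasetManifest,
    config: TrainConfig,
    crops: Optional[Sequence[DiatomCrop] | dict[str, np.ndarray]] = None,
    crop_dir=None,
) -> tuple[NetworkInstance, TrainLog]:
    """Train on the manifest's train split, early-stopping on validation."""
    labels = tuple(sorted({r.species for r in manifest.rows}))
    if len(labels) != net.spec.num_classes:
        raise ValueError(
            f"manifest has {len(labels)} classes but the network expects "
            f"{net.spec.num_classes}"
        )
    Xtr, ytr, _ = resolve_split_arrays(manifest, "train", crops, crop_dir, labels)
    Xva, yva, _ = resolve_split_arrays(manifest, "validation", crops, crop_dir, labels)
    return train_arrays(net, Xtr, ytr, Xva, yva, config)
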