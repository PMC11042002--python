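"""Confusion matrices and support-weighted multiclass metrics.

The dataset is strongly unbalanced (class sizes 6-386), so headline numbers
are support-weighted averages: for metric ``m`` with per-class values
``m_c`` and supports ``n_c``, the weighted value is ``sum_c (n_c / N) m_c``.
Per class, ``precision = TP / (TP + FP)``, ``recall = TP / (TP + FN)``,
``F = 2 P R / (P + R)``; overall ``accuracy = trace / N``.  Support-weighted
recall is algebraically identical to overall accuracy, which doubles as an
internal consistency check.  Zero-denominator per-class values are set to 0
and flagged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .datasets import DatasetManifest
from .network import NetworkInstance
from .preprocess import DiatomCrop
from .training import resolve_split_arrays
from . import engine as E

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "confusion_from_predictions",
    "report_from_confusion",
    "evaluate",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with rows = true class, columns = predicted class."""

    counts: np.ndarray  # (C, C) int
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        c = self.counts
        if c.ndim != 2 or c.shape[0] != c.shape[1] or c.shape[0] != len(self.labels):
            raise ValueError("confusion matrix must be CxC with matching labels")
        if (c < 0).any():
            raise ValueError("confusion matrix entries must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class EvalReport:
    per_class: tuple[tuple[str, float, float, float, int], ...]  # (label, P, R, F, support)
    weighted: dict[str, float]  # accuracy, precision, recall, f_measure
    confusion: ConfusionMatrix
    zero_division_classes: tuple[str, ...] = ()

    def to_json(self) -> str:
        return json.dumps(
            {
                "weighted": self.weighted,
                "per_class": [
                    {"label": l, "precision": p, "recall": r, "f_measure": f, "support": s}
                    for l, p, r, f, s in self.per_class
                ],
                "confusion": self.confusion.counts.tolist(),
                "labels": list(self.confusion.labels),
                "zero_division_classes": list(self.zero_division_classes),
            },
            indent=2,
        )

    def to_text(self) -> str:
        lines = [
            f"{'class':<28}{'precision':>10}{'recall':>10}{'F':>10}{'support':>9}"
        ]
        for l, p, r, f, s in self.per_class:
            lines.append(f"{l:<28}{p:>10.4f}{r:>10.4f}{f:>10.4f}{s:>9d}")
        w = self.weighted
        lines.append(
            f"{'weighted':<28}{w['precision']:>10.4f}{w['recall']:>10.4f}"
            f"{w['f_measure']:>10.4f}{self.confusion.total:>9d}"
        )
        lines.append(f"accuracy: {w['accuracy']:.4f}")
        if self.zero_division_classes:
            lines.append(
                "zero-division (metric set to 0): " + ", ".join(self.zero_division_classes)
            )
        return "\n".join(lines)


def confusion_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray, labels: tuple[str, ...]
) -> ConfusionMatrix:
    c = len(labels)
    counts = np.zeros((c, c), dtype=np.int64)
    np.add.at(counts, (np.asarray(y_true), np.asarray(y_pred)), 1)
    return ConfusionMatrix(counts=counts, labels=labels)


def report_from_confusion(cm: ConfusionMatrix) -> EvalReport:
    counts = cm.counts.astype(np.float64)
    n = counts.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(counts)
    support = counts.sum(axis=1)
    predicted = counts.sum(axis=0)

    zero_flags: list[str] = []
    precision = np.zeros(len(cm.labels))
    recall = np.zeros(len(cm.labels))
    f_measure = np.zeros(len(cm.labels))
    for i, label in enumerate(cm.labels):
        if predicted[i] > 0:
            precision[i] = tp[i] / predicted[i]
        else:
            zero_flags.append(label)
        if support[i] > 0:
            recall[i] = tp[i] / support[i]
        if precision[i] + recall[i] > 0:
            f_measure[i] = 2 * precision[i] * recall[i] / (precision[i] + recall[i])

    weight = support / n
    weighted = {
        "accuracy": float(tp.sum() / n),
        "precision": float((weight * precision).sum()),
        "recall": float((weight * recall).sum()),
        "f_measure": float((weight * f_measure).sum()),
    }
    per_class = tuple(
        (label, float(precision[i]), float(recall[i]), float(f_measure[i]), int(support[i]))
        for i, label in enumerate(cm.labels)
    )
    return EvalReport(
        per_class=per_class,
        weighted=weighted,
        confusion=cm,
        zero_division_classes=tuple(zero_flags),
    )


def evaluate(
    net: NetworkInstance,
    manifest: DatasetManifest,
    split: str = "test",
    crops: Optional[Sequence[DiatomCrop] | dict[str, np.ndarray]] = None,
    crop_dir=None,
    batch_size: int = 32,
) -> EvalReport:
    """Run the network on one split (inference mode) and score it."""
    labels = tuple(sorted({r.species for r in manifest.rows}))
    if len(labels) != net.spec.num_classes:
        raise ValueError(
            f"label mismatch: manifest has {len(labels)} classes, network expects "
            f"{net.spec.num_classes}"
        )
    X, y, _ = resolve_split_arrays(manifest, split, crops, crop_dir, labels)
    preds = np.empty(len(X), dtype=np.int64)
    for i in range(0, len(X), batch_size):
        xb = net._to_input_batch(X[i : i + batch_size])
        logits = net.forward_logits(xb, training=False)
        preds[i : i + len(xb)] = logits.argmax(axis=1)
    cm = confusion_from_predictions(y, preds, labels)
    return report_from_confusion(cm)
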