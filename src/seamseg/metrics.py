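"""Pixel-level segmentation metrics and the BCE + Dice composite loss.

All mask metrics are computed from the 2x2 confusion matrix (TP, FP, TN,
FN) of a binary prediction against a binary reference:

    precision = TP / (TP + FP)        recall = TP / (TP + FN)
    accuracy  = (TP + TN) / total
    IoU       = |A ∩ B| / |A ∪ B|     Dice = 2|A ∩ B| / (|A| + |B|)

Conventions for degenerate denominators: precision/recall return 0 with a
warning when undefined; IoU/Dice return 1 when both masks are empty.
Aggregation over a dataset is micro-averaged (counts summed before the
ratios are taken).
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from . import autograd as ag
from .autograd import Tensor

METRIC_NAMES = ("precision", "recall", "accuracy", "iou", "dice")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


def _as_binary(mask, name: str) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.dtype == bool:
        return arr
    vals = np.unique(arr)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"{name} must be binary (0/1), found values {vals[:5]}")
    return arr.astype(bool)


def confusion_counts(pred_mask, true_mask) -> ConfusionCounts:
    """Tabulate per-pixel TP/FP/TN/FN of two equally shaped binary masks."""
    p = _as_binary(pred_mask, "pred_mask")
    t = _as_binary(true_mask, "true_mask")
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _safe_ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what} undefined (zero denominator); returning 0",
                      RuntimeWarning, stacklevel=3)
        return 0.0
    return num / den


def precision(c: ConfusionCounts) -> float:
    return _safe_ratio(c.tp, c.tp + c.fp, "precision")


def recall(c: ConfusionCounts) -> float:
    return _safe_ratio(c.tp, c.tp + c.fn, "recall")


def accuracy(c: ConfusionCounts) -> float:
    return _safe_ratio(c.tp + c.tn, c.total, "accuracy")


def iou_from_counts(c: ConfusionCounts) -> float:
    union = c.tp + c.fp + c.fn
    if union == 0:
        return 1.0
    return c.tp / union


def dice_from_counts(c: ConfusionCounts) -> float:
    den = 2 * c.tp + c.fp + c.fn
    if den == 0:
        return 1.0
    return 2 * c.tp / den


def iou(pred_mask, true_mask) -> float:
    return iou_from_counts(confusion_counts(pred_mask, true_mask))


def dice(pred_mask, true_mask) -> float:
    return dice_from_counts(confusion_counts(pred_mask, true_mask))


def metrics_from_counts(c: ConfusionCounts) -> dict[str, float]:
    return {
        "precision": precision(c),
        "recall": recall(c),
        "accuracy": accuracy(c),
        "iou": iou_from_counts(c),
        "dice": dice_from_counts(c),
    }


# ---------------------------------------------------------------------------
# training loss
# ---------------------------------------------------------------------------

def bce_dice_loss(prob_map, true_mask, w_bce: float = 0.5, w_dice: float = 1.0,
                  eps: float = 1e-7, smooth: float = 1e-5) -> Tensor:
    """Weighted binary cross-entropy + soft-Dice loss.

    ``loss = w_bce * BCE(p, t) + w_dice * (1 - softDice(p, t))`` with
    ``softDice = (2 Σ p t + smooth) / (Σ p + Σ t + smooth)`` summed over the
    whole batch.  ``prob_map`` holds probabilities (already sigmoided); it
    is clipped to [eps, 1 - eps] inside the BCE term.  Differentiable in
    ``prob_map`` when it is a :class:`Tensor`.
    """
    p = ag.as_tensor(prob_map, np.float32 if not isinstance(prob_map, Tensor) else None)
    t = ag.as_tensor(np.asarray(true_mask, dtype=p.dtype))
    if np.isnan(p.data).any():
        raise FloatingPointError("NaN in probability map")
    pc = ag.clip(p, eps, 1.0 - eps)
    bce = -(t * ag.log(pc) + (1.0 - t) * ag.log(1.0 - pc)).mean()
    inter = (p * t).sum()
    soft_dice = (2.0 * inter + smooth) / (p.sum() + t.sum() + smooth)
    return w_bce * bce + w_dice * (1.0 - soft_dice)


def soft_dice(prob_map, true_mask, smooth: float = 1e-5) -> float:
    """Soft Dice coefficient of a probability map against a binary mask."""
    p = np.asarray(prob_map.data if isinstance(prob_map, Tensor) else prob_map,
                   dtype=np.float64)
    t = np.asarray(true_mask, dtype=np.float64)
    return float((2 * (p * t).sum() + smooth) / (p.sum() + t.sum() + smooth))


# ---------------------------------------------------------------------------
# dataset-level evaluation
# ---------------------------------------------------------------------------

@dataclass
class MetricReport:
    """Per-image confusion counts and metrics plus a micro-averaged aggregate."""

    per_image: list[dict] = field(default_factory=list)
    aggregate: dict[str, float] = field(default_factory=dict)
    counts: ConfusionCounts | None = None

    def to_json(self, path) -> None:
        payload = {"per_image": self.per_image, "aggregate": self.aggregate,
                   "counts": asdict(self.counts) if self.counts else None}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def to_csv(self, path) -> None:
        cols = ["image"] + list(METRIC_NAMES)
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=cols, extrasaction="ignore")
            writer.writeheader()
            for row in self.per_image:
                writer.writerow(row)
            writer.writerow({"image": "aggregate", **self.aggregate})


def evaluate_masks(pred_masks, true_masks, names=None) -> MetricReport:
    """Micro-averaged report for parallel lists of binary masks."""
    preds = list(pred_masks)
    trues = list(true_masks)
    if len(preds) == 0:
        raise ValueError("cannot evaluate an empty dataset")
    if len(preds) != len(trues):
        raise ValueError("prediction/reference count mismatch")
    names = names or [str(i) for i in range(len(preds))]
    report = MetricReport()
    total = ConfusionCounts(0, 0, 0, 0)
    for name, p, t in zip(names, preds, trues):
        c = confusion_counts(p, t)
        total = total + c
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            row = {"image": name, **metrics_from_counts(c)}
        report.per_image.append(row)
    report.counts = total
    report.aggregate = metrics_from_counts(total)
    return report


def evaluate_dataset(model, pairs, threshold: float = 0.5,
                     batch_size: int = 8) -> MetricReport:
    """Evaluate a segmentation model on :class:`ImageMaskPair` items.

    Probabilities are binarized at ``threshold``; confusion counts are
    summed over images before the aggregate metrics are computed.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("cannot evaluate an empty dataset")
    images = np.stack([np.transpose(p.image, (2, 0, 1)) for p in pairs])
    probs = model.predict_proba(images.astype(np.float32), batch_size=batch_size)
    preds = [probs[i, 0] >= threshold for i in range(len(pairs))]
    trues = [p.mask.astype(bool) for p in pairs]
    names = [p.meta.get("name", str(i)) for i, p in enumerate(pairs)]
    return evaluate_masks(preds, trues, names)
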