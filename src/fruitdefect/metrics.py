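"""Evaluation statistics: recognition accuracy, IoU, Dice, FPR, FNR.

All five derive from TP/FP/FN/TN confusion counts and are reported as
percentages:

    recognition accuracy = TP / (TP + FN) * 100
    IoU                  = TP / (TP + FP + FN) * 100
    Dice                 = 2 TP / (2 TP + FP + FN) * 100
    FPR                  = FP / (FP + TN) * 100
    FNR                  = FN / (FN + TP) * 100

Counts come either per pixel (within an evaluation domain, normally the
fruit mask, so the image background cannot inflate TN) or per region, where
predicted and true components are matched greedily one-to-one by descending
IoU with a minimum-overlap acceptance threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ExtentMismatchError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int
    level: str = "pixel"  # {"pixel", "region"}

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class MetricSet:
    """Percentages; a metric whose denominator is zero is None (undefined)."""

    recognition_accuracy: float | None
    iou: float | None
    dice: float | None
    fpr: float | None
    fnr: float | None

    def as_dict(self) -> dict:
        return {
            "recognition_accuracy": self.recognition_accuracy,
            "iou": self.iou,
            "dice": self.dice,
            "fpr": self.fpr,
            "fnr": self.fnr,
        }


def pixel_confusion(pred: np.ndarray, truth: np.ndarray, domain: np.ndarray | None = None) -> ConfusionCounts:
    """Per-pixel confusion counts, restricted to ``domain`` (default: everywhere)."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ExtentMismatchError("prediction and truth extents differ")
    if domain is None:
        domain = np.ones_like(pred)
    else:
        domain = np.asarray(domain, dtype=bool)
        if domain.shape != pred.shape:
            raise ExtentMismatchError("domain extent differs")
    p = pred[domain]
    t = truth[domain]
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn, level="pixel")


def _as_mask_list(components) -> list[np.ndarray]:
    """Accept a labeled int array or a list of boolean masks."""
    if isinstance(components, np.ndarray) and components.ndim == 2 and not components.dtype == bool:
        return [components == lab for lab in np.unique(components) if lab != 0]
    return [np.asarray(m, dtype=bool) for m in components]


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    union = np.count_nonzero(a | b)
    if union == 0:
        return 0.0
    return np.count_nonzero(a & b) / union


def region_confusion(pred_components, truth_components, match_iou: float = 0.3) -> ConfusionCounts:
    """Region-level confusion via greedy one-to-one IoU matching.

    Pairs are taken in order of descending IoU; a pair with IoU >=
    ``match_iou`` whose members are both unmatched becomes a TP.  Unmatched
    true components are FN, unmatched predictions FP.  TN is undefined at
    region level and reported as 0 (FPR is then unavailable).
    """
    preds = _as_mask_list(pred_components)
    truths = _as_mask_list(truth_components)
    pairs = []
    for i, p in enumerate(preds):
        for j, t in enumerate(truths):
            iou = mask_iou(p, t)
            if iou >= match_iou:
                pairs.append((iou, i, j))
    pairs.sort(key=lambda x: (-x[0], x[1], x[2]))
    used_p: set[int] = set()
    used_t: set[int] = set()
    tp = 0
    for _, i, j in pairs:
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
        tp += 1
    return ConfusionCounts(tp=tp, fp=len(preds) - tp, fn=len(truths) - tp, tn=0, level="region")


def _pct(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def metrics(counts: ConfusionCounts) -> MetricSet:
    """Apply the five formulas to a set of confusion counts."""
    return MetricSet(
        recognition_accuracy=_pct(counts.tp, counts.tp + counts.fn),
        iou=_pct(counts.tp, counts.tp + counts.fp + counts.fn),
        dice=_pct(2 * counts.tp, 2 * counts.tp + counts.fp + counts.fn),
        fpr=_pct(counts.fp, counts.fp + counts.tn),
        fnr=_pct(counts.fn, counts.fn + counts.tp),
    )
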