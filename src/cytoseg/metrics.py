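"""Object-level and pixel-level segmentation evaluation.

Object level: predictions are matched one-to-one to ground-truth instances
greedily by descending mask IoU at a threshold ``match_iou``; matches are
true positives, unmatched predictions false positives, unmatched ground
truths false negatives.  Pixel level: Dice, Jaccard and plain pixel accuracy
on binary masks.

Empty-denominator conventions (fixed so every report is well defined):
precision is 0 when there are no predictions but ground truth exists;
recall is 0 in the mirrored case; every metric is 1 when prediction and
ground truth are both empty.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np

from .fusion import match_instances
from .imgio import InstanceLabelMap

__all__ = ["EvalReport", "object_metrics", "pixel_metrics", "dice_score"]


@dataclass
class EvalReport:
    object_precision: float = 1.0
    object_recall: float = 1.0
    object_f1: float = 1.0
    pixel_dice: float = 1.0
    pixel_jaccard: float = 1.0
    pixel_accuracy: float = 1.0
    tp: int = 0
    fp: int = 0
    fn: int = 0
    match_iou: float = 0.5

    def to_csv(self, path: str | Path) -> None:
        names = [f.name for f in fields(self)]
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(names)
            writer.writerow([getattr(self, n) for n in names])

    def pretty(self) -> str:
        lines = ["segmentation evaluation", "-" * 23]
        for f in fields(self):
            v = getattr(self, f.name)
            lines.append(f"{f.name:>16}: {v:.4f}" if isinstance(v, float) else f"{f.name:>16}: {v}")
        return "\n".join(lines)


def object_metrics(
    pred: InstanceLabelMap, gt: InstanceLabelMap, match_iou: float = 0.5
) -> EvalReport:
    if pred.shape != gt.shape:
        raise ValueError("prediction and ground truth must share a shape")
    matches, unmatched_pred, unmatched_gt = match_instances(pred, gt, match_iou)
    tp, fp, fn = len(matches), len(unmatched_pred), len(unmatched_gt)
    if tp + fp + fn == 0:
        precision = recall = f1 = 1.0
    else:
        precision = tp / (tp + fp) if (tp + fp) else 0.0
        recall = tp / (tp + fn) if (tp + fn) else 0.0
        f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return EvalReport(
        object_precision=precision, object_recall=recall, object_f1=f1,
        tp=tp, fp=fp, fn=fn, match_iou=match_iou,
    )


def pixel_metrics(pred_binary: np.ndarray, gt_binary: np.ndarray) -> tuple[float, float, float]:
    """Return ``(dice, jaccard, accuracy)`` for two binary masks."""
    p = np.asarray(pred_binary, dtype=bool)
    g = np.asarray(gt_binary, dtype=bool)
    if p.shape != g.shape:
        raise ValueError("masks must share a shape")
    inter = int(np.logical_and(p, g).sum())
    union = int(np.logical_or(p, g).sum())
    size_sum = int(p.sum()) + int(g.sum())
    dice = 2.0 * inter / size_sum if size_sum else 1.0
    jaccard = inter / union if union else 1.0
    accuracy = float((p == g).mean())
    return dice, jaccard, accuracy


def dice_score(pred_binary: np.ndarray, gt_binary: np.ndarray) -> float:
    return pixel_metrics(pred_binary, gt_binary)[0]


def full_report(
    pred: InstanceLabelMap, gt: InstanceLabelMap, match_iou: float = 0.5
) -> EvalReport:
    """Object metrics plus pixel metrics on the foreground supports."""
    rep = object_metrics(pred, gt, match_iou)
    dice, jac, acc = pixel_metrics(pred.labels > 0, gt.labels > 0)
    rep.pixel_dice, rep.pixel_jaccard, rep.pixel_accuracy = dice, jac, acc
    return rep
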