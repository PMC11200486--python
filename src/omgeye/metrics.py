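"""Evaluation metrics for multi-class eye segmentation.

Area metrics (IoU, Dice, precision, recall, F1) are computed per class from
pixel confusion counts and averaged over a configurable class set — by
default all five classes.  The boundary metric MBIOU restricts the hard IoU
to pixels within a band of half-width ``d`` around class boundaries (union
of the ground-truth and prediction bands) and is averaged over the four
ocular classes, matching the class set the boundary loss attends to.

Ratios with an empty denominator (a class absent from prediction and ground
truth alike) score 1, consistent with the loss-side convention.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .losses import NON_SKIN_CLASSES, boundary_band
from .mask import CLASS_NAMES, LabelMask, confusion

__all__ = ["MetricReport", "segmentation_metrics", "mbiou", "timed"]

ALL_CLASSES: tuple[int, ...] = (0, 1, 2, 3, 4)


def _ratio(num: float, den: float) -> float:
    return 1.0 if den <= 0 else num / den


@dataclass(frozen=True)
class MetricReport:
    """Per-class and mean segmentation quality scores, each in [0, 1]."""

    per_class: dict[int, dict[str, float]]
    means: dict[str, float]
    avg_time_s: float | None = None

    def as_dict(self) -> dict:
        return {
            "per_class": {
                CLASS_NAMES[c] if c < len(CLASS_NAMES) else str(c): dict(v)
                for c, v in self.per_class.items()
            },
            "means": dict(self.means),
            "avg_time_s": self.avg_time_s,
        }


def segmentation_metrics(
    pred: LabelMask,
    gt: LabelMask,
    class_set: Sequence[int] = ALL_CLASSES,
) -> MetricReport:
    """IoU, Dice, precision, recall and F1 per class plus their means.

    F1 is reported alongside Dice even though the two coincide per class
    (2tp / (2tp + fp + fn)); both names are in common use for this task.
    """
    counts = confusion(pred, gt)
    per_class: dict[int, dict[str, float]] = {}
    for c in class_set:
        tp, fp, fn = int(counts.tp[c]), int(counts.fp[c]), int(counts.fn[c])
        precision = _ratio(tp, tp + fp)
        recall = _ratio(tp, tp + fn)
        # harmonic mean computed from counts so the 0/0 -> 1 convention is
        # applied once, keeping the per-class F1 = Dice identity exact
        f1 = _ratio(2 * tp, 2 * tp + fp + fn)
        per_class[c] = {
            "iou": _ratio(tp, tp + fp + fn),
            "dice": _ratio(2 * tp, 2 * tp + fp + fn),
            "precision": precision,
            "recall": recall,
            "f1": f1,
        }
    means = {
        f"m{k}": float(np.mean([per_class[c][k] for c in class_set]))
        for k in ("iou", "dice", "precision", "recall", "f1")
    }
    return MetricReport(per_class=per_class, means=means)


def mbiou(
    pred: LabelMask,
    gt: LabelMask,
    d: int,
    class_set: Sequence[int] = NON_SKIN_CLASSES,
) -> float:
    """Mean boundary IoU: hard per-class IoU on the boundary band only.

    The band is the union of the ground-truth and prediction boundary bands
    of half-width ``d``; with ``d`` at least the image diagonal the band
    saturates to the whole image and MBIOU collapses to the plain mean IoU
    over the same class set.
    """
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    if d < 1:
        raise ValueError("band half-width d must be >= 1")
    band = boundary_band(gt, d) | boundary_band(pred, d)
    g = gt.labels[band]
    p = pred.labels[band]
    ious = []
    for c in class_set:
        gc = g == c
        pc = p == c
        union = int(gc.sum()) + int(pc.sum()) - int((gc & pc).sum())
        ious.append(_ratio(int((gc & pc).sum()), union))
    return float(np.mean(ious))


def timed(fn: Callable, inputs: Sequence) -> tuple[list, float]:
    """Apply ``fn`` to each input, returning results and the mean wall time.

    Timing is hardware-dependent and reported for bookkeeping only.
    """
    if len(inputs) == 0:
        raise ValueError("inputs must be non-empty")
    results = []
    elapsed = 0.0
    for x in inputs:
        t0 = time.perf_counter()
        results.append(fn(x))
        elapsed += time.perf_counter() - t0
    return results, elapsed / len(inputs)
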