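"""Segmentation loss functions: global, local, boundary, and scheduled hybrids.

Five losses are provided for the 5-class eye-mask task:

* cross entropy (CE) — a *global* loss over all pixels,
* weighted cross entropy (WCE) — CE with per-class weights,
* soft IoU and soft Dice — *local* losses over the per-class overlap sums,
* boundary loss — the soft-IoU form restricted to a band of half-width
  ``d`` around class boundaries, averaged over the four ocular classes
  (pupil, iris, sclera, caruncle); the surrounding skin is excluded since
  its boundary is shared with them.

Writing ``y_ij`` for the one-hot ground truth of pixel *i* on class *j* and
``p_ij`` for the predicted probability, with ``N`` pixels and ``m`` classes:

    L_CE   = -(1/N) sum_i sum_j y_ij log p_ij
    L_WCE  = -(1/N) sum_i sum_j w_j y_ij log p_ij
    L_IoU  = 1 - (1/m) sum_j  I_j / (Y_j + P_j - I_j)
    L_Dice = 1 - (1/m) sum_j  2 I_j / (Y_j + P_j)

where ``I_j = sum_i y_ij p_ij``, ``Y_j = sum_i y_ij``, ``P_j = sum_i p_ij``.
The boundary loss is L_IoU with the pixel index restricted to the union of
the ground-truth band G_d and the prediction band P_d.  A class absent from
both masks contributes a perfect per-class ratio of 1 (no penalty).

The hybrid loss is ``alpha * L_global + beta * L_local + gamma(e) * L_boundary``
with ``gamma`` ramping linearly from 0 to ``gamma_max`` across training
epochs, so the boundary term only takes over once the global/local terms
have shaped a reasonable segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .mask import (
    N_CLASSES,
    ClassWeights,
    LabelMask,
    ProbMap,
    argmax_mask,
)

__all__ = [
    "LOG_EPS",
    "NON_SKIN_CLASSES",
    "BandSpec",
    "HybridLossConfig",
    "ce_loss",
    "wce_loss",
    "iou_loss",
    "dice_loss",
    "boundary_pixels",
    "boundary_band",
    "boundary_loss",
    "gamma_schedule",
    "hybrid_loss",
    "inverse_frequency_weights",
]

#: Probabilities are clipped to [LOG_EPS, 1] inside logarithms.
LOG_EPS = 1e-7

#: The four ocular structure classes the boundary loss attends to.
NON_SKIN_CLASSES: tuple[int, ...] = (1, 2, 3, 4)


@dataclass(frozen=True)
class BandSpec:
    """Boundary band of half-width ``d`` px with its derived binary mask."""

    d: int
    band_mask: np.ndarray

    def __post_init__(self) -> None:
        if int(self.d) != self.d or self.d < 1:
            raise ValueError("band half-width d must be an integer >= 1")
        object.__setattr__(self, "d", int(self.d))
        object.__setattr__(self, "band_mask", np.asarray(self.band_mask, dtype=bool))


@dataclass(frozen=True)
class HybridLossConfig:
    """Configuration of the scheduled hybrid loss.

    Attributes
    ----------
    alpha, beta : weights of the global and local terms (default 1 each).
    gamma_max : terminal boundary weight reached at the last epoch.
    global_term : "ce" or "wce".
    local_term : "iou", "dice" or "none".
    schedule : ramp shape for gamma; only "linear" is defined.
    total_epochs : length of the training run the ramp spans.
    d : boundary-band half-width in px.
    """

    alpha: float = 1.0
    beta: float = 1.0
    gamma_max: float = 1.0
    global_term: str = "ce"
    local_term: str = "dice"
    schedule: str = "linear"
    total_epochs: int = 150
    d: int = 2

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0 or self.gamma_max < 0:
            raise ValueError("loss weights must be non-negative")
        if self.total_epochs < 1:
            raise ValueError("total_epochs must be >= 1")
        if self.global_term not in ("ce", "wce"):
            raise ValueError("global_term must be 'ce' or 'wce'")
        if self.local_term not in ("iou", "dice", "none"):
            raise ValueError("local_term must be 'iou', 'dice' or 'none'")
        if self.schedule != "linear":
            raise ValueError("only the linear gamma schedule is defined")
        if self.local_term == "none" and self.beta > 0:
            raise ValueError("beta > 0 requires a local term")


def _check_shapes(pred: ProbMap, gt: LabelMask) -> None:
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    if gt.labels.max() >= pred.n_classes:
        raise ValueError("gt contains a class id outside the prediction's classes")


def _one_hot_arr(gt: LabelMask, m: int) -> np.ndarray:
    eye = np.eye(m, dtype=float)
    return eye[gt.labels]


def ce_loss(pred: ProbMap, gt: LabelMask) -> float:
    """Mean per-pixel cross entropy between prediction and ground truth."""
    _check_shapes(pred, gt)
    rows, cols = np.indices(gt.shape)
    p_true = pred.probs[rows, cols, gt.labels]
    return float(-np.mean(np.log(np.clip(p_true, LOG_EPS, 1.0))))


def wce_loss(pred: ProbMap, gt: LabelMask, weights: ClassWeights) -> float:
    """Class-weighted cross entropy; reduces to :func:`ce_loss` at unit weights."""
    _check_shapes(pred, gt)
    if len(weights) != pred.n_classes:
        raise ValueError(
            f"expected {pred.n_classes} class weights, got {len(weights)}"
        )
    rows, cols = np.indices(gt.shape)
    p_true = pred.probs[rows, cols, gt.labels]
    w = weights.weights[gt.labels]
    return float(-np.mean(w * np.log(np.clip(p_true, LOG_EPS, 1.0))))


def _soft_overlap_terms(
    pred: ProbMap, gt: LabelMask, pixel_mask: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-class (I_j, Y_j, P_j) sums, optionally over a restricted pixel set."""
    y = _one_hot_arr(gt, pred.n_classes)
    p = pred.probs
    if pixel_mask is not None:
        y = y[pixel_mask]
        p = p[pixel_mask]
    else:
        y = y.reshape(-1, pred.n_classes)
        p = p.reshape(-1, pred.n_classes)
    inter = (y * p).sum(axis=0)
    return inter, y.sum(axis=0), p.sum(axis=0)


def _mean_ratio(num: np.ndarray, den: np.ndarray, classes: Iterable[int]) -> float:
    # empty-class convention: 0/0 -> ratio 1 (no penalty for an absent class)
    classes = list(classes)
    ratios = []
    for j in classes:
        ratios.append(1.0 if den[j] <= 0 else num[j] / den[j])
    return float(np.mean(ratios))


def iou_loss(
    pred: ProbMap, gt: LabelMask, class_set: Sequence[int] | None = None
) -> float:
    """Soft IoU loss averaged over classes (all classes by default)."""
    _check_shapes(pred, gt)
    classes = range(pred.n_classes) if class_set is None else class_set
    inter, ysum, psum = _soft_overlap_terms(pred, gt)
    return 1.0 - _mean_ratio(inter, ysum + psum - inter, classes)


def dice_loss(
    pred: ProbMap, gt: LabelMask, class_set: Sequence[int] | None = None
) -> float:
    """Soft Dice loss; never exceeds the soft IoU loss on the same input."""
    _check_shapes(pred, gt)
    classes = range(pred.n_classes) if class_set is None else class_set
    inter, ysum, psum = _soft_overlap_terms(pred, gt)
    return 1.0 - _mean_ratio(2.0 * inter, ysum + psum, classes)


def boundary_pixels(mask: LabelMask) -> np.ndarray:
    """Pixels having a 4-neighbor with a different class id.

    The image frame itself is not a boundary: a uniform mask has none.
    """
    lab = mask.labels
    out = np.zeros(lab.shape, dtype=bool)
    out[:-1, :] |= lab[:-1, :] != lab[1:, :]
    out[1:, :] |= lab[1:, :] != lab[:-1, :]
    out[:, :-1] |= lab[:, :-1] != lab[:, 1:]
    out[:, 1:] |= lab[:, 1:] != lab[:, :-1]
    return out


def boundary_band(mask: LabelMask, d: int) -> np.ndarray:
    """Binary band of all pixels within Euclidean distance ``d`` of a boundary."""
    if d < 1:
        raise ValueError("band half-width d must be >= 1")
    edge = boundary_pixels(mask)
    if not edge.any():
        return np.zeros(mask.shape, dtype=bool)
    dist = ndimage.distance_transform_edt(~edge)
    return dist <= d


def band_spec(mask: LabelMask, d: int) -> BandSpec:
    """Bundle a band half-width with its derived mask."""
    return BandSpec(d=d, band_mask=boundary_band(mask, d))


def boundary_loss(
    pred: ProbMap,
    gt: LabelMask,
    d: int,
    class_set: Sequence[int] = NON_SKIN_CLASSES,
) -> float:
    """Soft IoU loss restricted to the boundary band of half-width ``d``.

    The band is the union of the ground-truth band G_d and the prediction
    band P_d (prediction boundaries taken from the argmax labels), which
    makes the loss symmetric under swapping hard predictions with labels.
    An image with no class boundaries at all yields 0.
    """
    _check_shapes(pred, gt)
    band = boundary_band(gt, d) | boundary_band(argmax_mask(pred), d)
    if not band.any():
        return 0.0
    inter, ysum, psum = _soft_overlap_terms(pred, gt, pixel_mask=band)
    classes = [j for j in class_set if j < pred.n_classes]
    return 1.0 - _mean_ratio(inter, ysum + psum - inter, classes)


def gamma_schedule(epoch: int, total_epochs: int, gamma_max: float = 1.0) -> float:
    """Linear boundary-weight ramp: 0 at the first epoch, gamma_max at the last."""
    if not 0 <= epoch < total_epochs:
        raise ValueError(f"epoch {epoch} outside [0, {total_epochs})")
    if total_epochs == 1:
        return float(gamma_max)
    return float(gamma_max * epoch / (total_epochs - 1))


def hybrid_loss(
    pred: ProbMap,
    gt: LabelMask,
    cfg: HybridLossConfig,
    epoch: int,
    weights: ClassWeights | None = None,
) -> float:
    """Scheduled combination alpha*global + beta*local + gamma(epoch)*boundary.

    Terms with zero weight (or ``local_term='none'``) are skipped entirely,
    so e.g. a pure "G + B" mode never evaluates a local loss.
    """
    total = 0.0
    if cfg.alpha > 0:
        if cfg.global_term == "ce":
            total += cfg.alpha * ce_loss(pred, gt)
        else:
            w = weights if weights is not None else inverse_frequency_weights(gt, pred.n_classes)
            total += cfg.alpha * wce_loss(pred, gt, w)
    if cfg.beta > 0 and cfg.local_term != "none":
        local = iou_loss if cfg.local_term == "iou" else dice_loss
        total += cfg.beta * local(pred, gt)
    gamma = gamma_schedule(epoch, cfg.total_epochs, cfg.gamma_max)
    if gamma > 0:
        total += gamma * boundary_loss(pred, gt, cfg.d)
    return float(total)


def inverse_frequency_weights(gt: LabelMask, m: int = N_CLASSES) -> ClassWeights:
    """Inverse class-frequency weights normalized to mean 1.

    Classes absent from the mask receive the largest weight observed among
    present classes (they cannot dominate a mask they do not appear in).
    """
    counts = np.bincount(gt.labels.ravel(), minlength=m).astype(float)
    present = counts > 0
    inv = np.zeros(m)
    inv[present] = 1.0 / counts[present]
    if (~present).any():
        inv[~present] = inv[present].max()
    inv *= m / inv.sum()
    return ClassWeights(inv)
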