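"""Label masks, probability maps, and preprocessing primitives.

The segmentation task uses five classes: surrounding skin (0), pupil (1),
iris (2), sclera (3) and lacrimal caruncle (4).  Ground truth is stored as a
:class:`LabelMask`; network output as a :class:`ProbMap` of per-pixel class
probabilities.  Masks are exchanged on disk as palette PNGs with a fixed
color code (skin black, pupil green, iris red, sclera blue, caruncle
yellow); probability maps as ``.npz`` archives with arrays ``probs`` and
``classes``.

Coordinates are row-major and 0-based with the origin at the top-left;
rectangles are half-open ``(row0, col0, row1, col1)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

__all__ = [
    "CLASS_NAMES",
    "PALETTE",
    "N_CLASSES",
    "SKIN",
    "PUPIL",
    "IRIS",
    "SCLERA",
    "CARUNCLE",
    "LabelMask",
    "ProbMap",
    "ClassWeights",
    "ConfusionCounts",
    "read_mask_png",
    "write_mask_png",
    "read_probmap",
    "write_probmap",
    "one_hot",
    "argmax_mask",
    "confusion",
    "crop_eye",
    "hflip",
    "split_dataset",
]

SKIN, PUPIL, IRIS, SCLERA, CARUNCLE = 0, 1, 2, 3, 4
N_CLASSES = 5
CLASS_NAMES = ("skin", "pupil", "iris", "sclera", "caruncle")

#: RGB palette, index == class id.
PALETTE: tuple[tuple[int, int, int], ...] = (
    (0, 0, 0),        # skin
    (0, 255, 0),      # pupil
    (255, 0, 0),      # iris
    (0, 0, 255),      # sclera
    (255, 255, 0),    # caruncle
)


class MaskDecodeError(ValueError):
    """A mask PNG contains a pixel color outside the five-color palette."""


@dataclass(frozen=True)
class LabelMask:
    """A 2-D grid of integer class ids in ``{0..4}``.

    Parameters
    ----------
    labels : ndarray of shape (H, W), integer
        Per-pixel class ids.
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("labels must be a non-empty 2-D array")
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("labels must have an integer dtype")
        if arr.min() < 0 or arr.max() >= N_CLASSES:
            raise ValueError(f"class ids must lie in [0, {N_CLASSES - 1}]")
        object.__setattr__(self, "labels", arr)

    @property
    def height(self) -> int:
        return self.labels.shape[0]

    @property
    def width(self) -> int:
        return self.labels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabelMask):
            return NotImplemented
        return np.array_equal(self.labels, other.labels)

    def __hash__(self):  # pragma: no cover - frozen dataclass requirement
        return hash((self.labels.shape, self.labels.tobytes()))


@dataclass(frozen=True)
class ProbMap:
    """Per-pixel class probabilities of shape ``(H, W, m)``.

    Each pixel's probabilities must sum to 1 (within 1e-6) and lie in
    ``[0, 1]``; at least two classes are required.
    """

    probs: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.probs, dtype=float)
        if arr.ndim != 3 or arr.shape[2] < 2:
            raise ValueError("probs must be (H, W, m) with m >= 2")
        if arr.min() < -1e-9 or arr.max() > 1 + 1e-9:
            raise ValueError("probabilities must lie in [0, 1]")
        sums = arr.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("per-pixel probabilities must sum to 1")
        object.__setattr__(self, "probs", arr)

    @property
    def height(self) -> int:
        return self.probs.shape[0]

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @property
    def n_classes(self) -> int:
        return self.probs.shape[2]

    @property
    def shape(self) -> tuple[int, int]:
        return self.probs.shape[:2]


@dataclass(frozen=True)
class ClassWeights:
    """Non-negative per-class weights for the weighted cross entropy."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or w.size == 0:
            raise ValueError("weights must be a non-empty vector")
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        if not (w > 0).any():
            raise ValueError("weights must not all be zero")
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return self.weights.size


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-class pixel-level confusion counts (tp, fp, fn, tn)."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray

    def __post_init__(self) -> None:
        arrs = [np.asarray(a, dtype=np.int64) for a in (self.tp, self.fp, self.fn, self.tn)]
        if len({a.shape for a in arrs}) != 1:
            raise ValueError("count vectors must share a shape")
        if any((a < 0).any() for a in arrs):
            raise ValueError("counts must be non-negative")
        totals = arrs[0] + arrs[1] + arrs[2] + arrs[3]
        if totals.size and not (totals == totals.flat[0]).all():
            raise ValueError("tp+fp+fn+tn must equal N for every class")
        for name, a in zip(("tp", "fp", "fn", "tn"), arrs):
            object.__setattr__(self, name, a)

    @property
    def n_pixels(self) -> int:
        return int(self.tp[0] + self.fp[0] + self.fn[0] + self.tn[0])


# ---------------------------------------------------------------------------
# PNG / npz I/O


def read_mask_png(path: str | Path) -> LabelMask:
    """Read a palette-coded mask PNG into a :class:`LabelMask`.

    Every pixel must match one of the five palette colors exactly; a loud
    :class:`MaskDecodeError` naming the offending RGB triple and location is
    raised otherwise (no nearest-color fallback, so label noise cannot pass
    silently).
    """
    img = Image.open(path).convert("RGB")
    rgb = np.asarray(img, dtype=np.uint8)
    labels = np.full(rgb.shape[:2], -1, dtype=np.int64)
    for cid, color in enumerate(PALETTE):
        labels[(rgb == np.array(color, dtype=np.uint8)).all(axis=2)] = cid
    bad = np.argwhere(labels < 0)
    if bad.size:
        r, c = bad[0]
        raise MaskDecodeError(
            f"pixel at (row={r}, col={c}) has color {tuple(int(v) for v in rgb[r, c])}, "
            f"which is not in the mask palette {PALETTE}"
        )
    return LabelMask(labels)


def write_mask_png(mask: LabelMask, path: str | Path) -> None:
    """Write a :class:`LabelMask` as a palette PNG with the fixed color code."""
    img = Image.fromarray(mask.labels.astype(np.uint8), mode="P")
    flat_palette = [v for color in PALETTE for v in color]
    img.putpalette(flat_palette)
    img.save(path, format="PNG")


def write_probmap(pmap: ProbMap, path: str | Path) -> None:
    """Save a probability map as ``.npz`` with arrays ``probs`` and ``classes``."""
    np.savez(path, probs=pmap.probs, classes=np.arange(pmap.n_classes))


def read_probmap(path: str | Path) -> ProbMap:
    with np.load(path) as data:
        return ProbMap(data["probs"])


# ---------------------------------------------------------------------------
# Encoding and counting


def one_hot(mask: LabelMask, m: int = N_CLASSES) -> ProbMap:
    """One-hot encode a label mask into a degenerate probability map."""
    if mask.labels.max() >= m:
        raise ValueError(
            f"mask contains class id {int(mask.labels.max())} >= m={m}"
        )
    probs = np.zeros((*mask.shape, m), dtype=float)
    rows, cols = np.indices(mask.shape)
    probs[rows, cols, mask.labels] = 1.0
    return ProbMap(probs)


def argmax_mask(pmap: ProbMap) -> LabelMask:
    """Hard labels from a probability map; ties go to the lowest class id."""
    return LabelMask(np.argmax(pmap.probs, axis=2).astype(np.int64))


def confusion(pred: LabelMask, gt: LabelMask, m: int = N_CLASSES) -> ConfusionCounts:
    """Per-class pixel confusion counts between prediction and ground truth."""
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    n = pred.labels.size
    joint = np.bincount(
        (gt.labels.ravel() * m + pred.labels.ravel()).astype(np.int64),
        minlength=m * m,
    ).reshape(m, m)  # joint[g, p]
    tp = np.diag(joint).astype(np.int64)
    fn = joint.sum(axis=1) - tp   # gt == c, pred != c
    fp = joint.sum(axis=0) - tp   # pred == c, gt != c
    tn = n - tp - fn - fp
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


# ---------------------------------------------------------------------------
# Preprocessing


def crop_eye(
    image_dims: tuple[int, int],
    box: tuple[int, int, int, int],
    pad_frac: float = 0.25,
) -> tuple[int, int, int, int]:
    """Expand a half-open eye box by ``pad_frac`` of its side on all four sides.

    A detector's tight eye box is padded so that the lids, canthi and some
    surrounding skin are retained, then clipped to image bounds.  The default
    padding fraction of 0.25 keeps a generous margin around the fissure.

    Parameters
    ----------
    image_dims : (height, width)
    box : (row0, col0, row1, col1), half-open, inside the image
    pad_frac : non-negative padding fraction
    """
    h, w = image_dims
    r0, c0, r1, c1 = box
    if r1 <= r0 or c1 <= c0:
        raise ValueError(f"empty box {box}")
    if pad_frac < 0:
        raise ValueError("pad_frac must be >= 0")
    if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
        raise ValueError(f"box {box} not inside image {image_dims}")
    pad_r = pad_frac * (r1 - r0)
    pad_c = pad_frac * (c1 - c0)
    return (
        max(0, int(round(r0 - pad_r))),
        max(0, int(round(c0 - pad_c))),
        min(h, int(round(r1 + pad_r))),
        min(w, int(round(c1 + pad_c))),
    )


def hflip(mask: LabelMask, side_tag: str) -> tuple[LabelMask, str]:
    """Mirror a mask left-right and swap its eye-side tag.

    Horizontal flipping maps a left eye onto right-eye anatomy (and vice
    versa), which is how the training set is augmented; the side tag travels
    with the image so downstream left/right bookkeeping stays correct.
    """
    if side_tag not in ("left", "right"):
        raise ValueError("side_tag must be 'left' or 'right'")
    flipped = LabelMask(mask.labels[:, ::-1].copy())
    return flipped, ("right" if side_tag == "left" else "left")


def split_dataset(
    items: Sequence,
    ratio: float = 0.8,
    seed: int = 0,
    group_key=None,
) -> tuple[list, list]:
    """Deterministic train/test split, optionally subject-disjoint.

    ``ratio`` is the train fraction (0.8 reproduces a 4:1 split).  When
    ``group_key`` is given, all items sharing a key (e.g. one subject's
    images) land on the same side of the split, preventing identity leakage.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must lie in (0, 1)")
    items = list(items)
    if not items:
        raise ValueError("items must be non-empty")
    rng = np.random.default_rng(seed)
    if group_key is None:
        idx = rng.permutation(len(items))
        n_train = int(round(ratio * len(items)))
        train = [items[i] for i in sorted(idx[:n_train])]
        test = [items[i] for i in sorted(idx[n_train:])]
        return train, test
    groups: dict = {}
    for it in items:
        groups.setdefault(group_key(it), []).append(it)
    keys = sorted(groups, key=str)
    order = rng.permutation(len(keys))
    n_train_items = int(round(ratio * len(items)))
    train, test = [], []
    taken = 0
    for gi in order:
        bucket = groups[keys[gi]]
        if taken < n_train_items:
            train.extend(bucket)
            taken += len(bucket)
        else:
            test.extend(bucket)
    return train, test


def write_sidecar(path: str | Path, *, side: str | None = None, **meta) -> None:
    """Write a small JSON sidecar (side tag + free-form metadata) next to a mask."""
    payload = dict(meta)
    if side is not None:
        payload["side"] = side
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
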