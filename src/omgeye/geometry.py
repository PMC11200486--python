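"""Ocular indicators from a 5-class eye mask.

Three clinically grounded indicators are computed from a segmentation mask,
operationalizing the ocular items of the myasthenia-gravis scoring scales
(QMGS / ARS-MG):

* **eyelid distance** — the height of the palpebral fissure in pixels: the
  maximum vertical extent, over image columns, of pixels labeled pupil,
  iris or sclera (the caruncle sits in the canthus, not between the lids);
* **clock point** — the cornea is treated as a clock face and the hour band
  reached by the drooping upper lid is graded 0-4; the hour lines are laid
  out at 30-degree intervals on the fitted iris circle;
* **scleral area** — residual exposed sclera on the gaze side as a fraction
  of the whole eye area (pupil + iris + sclera + caruncle); in a lateral
  gaze a healthy eye rotates far enough that the gaze-side sclera almost
  vanishes, so a large residual indicates impaired eye movement.

Because the pupil and iris are physiologically quasi-circular, their raw
segmented regions are first regularized by direct least-squares ellipse
fitting; all distances and areas are in pixels (no mm calibration).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from skimage.draw import ellipse as draw_ellipse
from skimage.measure import EllipseModel, find_contours

from .mask import IRIS, PUPIL, SCLERA, SKIN, LabelMask

__all__ = [
    "EllipseParams",
    "IndicatorSet",
    "EllipseFitError",
    "CLOCK_GRADES",
    "fit_ellipse",
    "fit_circle",
    "regularize_mask",
    "eyelid_distance",
    "clock_point",
    "scleral_area",
    "compute_indicators",
]

#: Clinical grade of each clock band (12 o'clock = no coverage ... 6 = full).
CLOCK_GRADES: dict[str, int] = {
    "12": 0,
    "11-1": 0,
    "10-2": 1,
    "9-3": 2,
    "8-4": 3,
    "7-5": 4,
    "6": 4,
}

# Fraction of the iris diameter covered when the lid margin reaches each
# hour line (chord height of the 30-degree spaced hour lines on a circle).
# exact algebraic values so band edges land on representable numbers
# (math.cos(pi/3) is 0.5000000000000001, which breaks the tie rule)
_COS30 = math.sqrt(3) / 2
_COS60 = 0.5
_CLOCK_THRESHOLDS: tuple[tuple[float, str], ...] = (
    ((1 - _COS30) / 2, "12"),
    ((1 - _COS60) / 2, "11-1"),
    (0.5, "10-2"),
    ((1 + _COS60) / 2, "9-3"),
    ((1 + _COS30) / 2, "8-4"),
)


class EllipseFitError(ValueError):
    """Raised when an ellipse cannot be fitted to the given points."""


@dataclass(frozen=True)
class EllipseParams:
    """Ellipse in image coordinates: center (x, y), semi-axes a >= b, angle.

    The angle is the orientation of the major axis in radians, normalized
    to [0, pi).
    """

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    angle: float

    def __post_init__(self) -> None:
        a, b = self.semi_axes
        if not (a >= b > 0):
            raise ValueError("semi-axes must satisfy a >= b > 0")
        if not (0 <= self.angle < math.pi):
            raise ValueError("angle must lie in [0, pi)")

    @property
    def radius(self) -> float:
        """Radius of the circumscribing circle (major semi-axis)."""
        return self.semi_axes[0]

    @property
    def area(self) -> float:
        return math.pi * self.semi_axes[0] * self.semi_axes[1]


@dataclass(frozen=True)
class IndicatorSet:
    """The three ocular indicators plus their supporting pixel counts."""

    eyelid_distance_px: int
    clock_point: str
    clock_grade: int
    sclera_left_px: int
    sclera_right_px: int
    sclera_gaze_px: int
    eye_area_px: int
    sclera_proportion: float

    def __post_init__(self) -> None:
        if self.sclera_gaze_px > self.sclera_left_px + self.sclera_right_px:
            raise ValueError("gaze-side sclera cannot exceed the total sclera")
        if not 0 <= self.sclera_proportion <= 1:
            raise ValueError("sclera_proportion must lie in [0, 1]")
        if CLOCK_GRADES.get(self.clock_point) != self.clock_grade:
            raise ValueError(
                f"clock grade {self.clock_grade} inconsistent with band {self.clock_point!r}"
            )

    def as_dict(self) -> dict:
        return {
            "eyelid_distance_px": self.eyelid_distance_px,
            "clock_point": self.clock_point,
            "clock_grade": self.clock_grade,
            "sclera_left_px": self.sclera_left_px,
            "sclera_right_px": self.sclera_right_px,
            "sclera_gaze_px": self.sclera_gaze_px,
            "eye_area_px": self.eye_area_px,
            "sclera_proportion": self.sclera_proportion,
        }


def fit_ellipse(points: np.ndarray) -> EllipseParams:
    """Direct least-squares ellipse fit to a set of (x, y) points.

    Noise-free samples of an ellipse are recovered to machine precision.
    At least 5 points in non-degenerate position are required.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise EllipseFitError("points must be an (n, 2) array of (x, y)")
    if pts.shape[0] < 5:
        raise EllipseFitError(f"need at least 5 points, got {pts.shape[0]}")
    # center and scale for conditioning; translation and uniform scaling
    # commute with the conic fit (theta is unchanged)
    mu = pts.mean(axis=0)
    scale = float(pts.std())
    if scale <= 0:
        raise EllipseFitError("all points coincide")
    try:
        model = EllipseModel.from_estimate((pts - mu) / scale)
    except Exception as exc:  # numerical failure inside the conic solver
        raise EllipseFitError(f"ellipse estimation failed: {exc}") from exc
    if not model:
        raise EllipseFitError("degenerate point configuration; no ellipse fits")
    xc, yc = (float(v) * scale + m for v, m in zip(model.center, mu))
    a, b = (float(v) * scale for v in model.axis_lengths)
    theta = float(model.theta)
    if b > a:
        a, b = b, a
        theta += math.pi / 2
    theta %= math.pi
    if not np.isfinite([xc, yc, a, b, theta]).all() or b <= 0:
        raise EllipseFitError("fit did not converge to a valid ellipse")
    return EllipseParams(center=(xc, yc), semi_axes=(a, b), angle=theta)


def fit_circle(points: np.ndarray) -> EllipseParams:
    """Least-squares circle fit (algebraic init, geometric refinement).

    A circle is far better constrained than a general ellipse when only a
    partial arc is visible — the common situation for a lid-occluded iris —
    and the front-view iris is physiologically circular.  Returned as an
    :class:`EllipseParams` with equal semi-axes.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise EllipseFitError("need at least 3 (x, y) points for a circle fit")
    x, y = pts[:, 0], pts[:, 1]
    # Kasa algebraic fit: x^2 + y^2 = 2 cx x + 2 cy y + (r^2 - cx^2 - cy^2)
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x * x + y * y
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy = sol[0], sol[1]
    r = math.sqrt(max(sol[2] + cx * cx + cy * cy, 1e-12))

    def residual(p):
        return np.hypot(x - p[0], y - p[1]) - p[2]

    fit = least_squares(residual, x0=[cx, cy, r])
    cx, cy, r = fit.x
    if not np.isfinite([cx, cy, r]).all() or r <= 0:
        raise EllipseFitError("circle fit did not converge")
    return EllipseParams(center=(float(cx), float(cy)), semi_axes=(float(r), float(r)), angle=0.0)


def _region_boundary_points(region: np.ndarray) -> np.ndarray:
    """Subpixel (x, y) contour points of a binary region (0.5 iso-level)."""
    contours = find_contours(np.pad(region, 1).astype(float), 0.5)
    if not contours:
        return np.empty((0, 2))
    pts = np.vstack(contours) - 1.0  # undo padding; (row, col)
    return pts[:, ::-1].copy()  # -> (x, y)


def _unoccluded_points(pts: np.ndarray, occluder: np.ndarray) -> np.ndarray:
    """Drop contour points whose surrounding pixels touch the occluder mask.

    When a quasi-circular structure is clipped by the eyelids, the clipped
    stretch of its contour runs along skin; fitting an ellipse through it
    would flatten the recovered circle.  Points adjacent to any occluder
    pixel are excluded so only the true limbus/pupil arcs constrain the fit.
    """
    h, w = occluder.shape
    keep = np.ones(len(pts), dtype=bool)
    for dx, dy in ((0, 0), (0, 1), (1, 0), (1, 1)):
        cc = np.clip(np.floor(pts[:, 0] - 0.5).astype(int) + dx, 0, w - 1)
        rr = np.clip(np.floor(pts[:, 1] - 0.5).astype(int) + dy, 0, h - 1)
        keep &= ~occluder[rr, cc]
    return pts[keep]


def _fit_region_ellipse(
    region: np.ndarray,
    occluder: np.ndarray | None = None,
    circular: bool = False,
) -> EllipseParams | None:
    pts = _region_boundary_points(region)
    if occluder is not None and occluder.any():
        open_pts = _unoccluded_points(pts, occluder)
        if open_pts.shape[0] >= 8:
            pts = open_pts
    if pts.shape[0] < 5:
        return None
    try:
        return fit_circle(pts) if circular else fit_ellipse(pts)
    except EllipseFitError:
        return None


def _raster_ellipse(params: EllipseParams, shape: tuple[int, int]) -> np.ndarray:
    (xc, yc), (a, b) = params.center, params.semi_axes
    rr, cc = draw_ellipse(yc, xc, b, a, shape=shape, rotation=params.angle)
    out = np.zeros(shape, dtype=bool)
    out[rr, cc] = True
    return out


def _regularize(mask: LabelMask) -> tuple[LabelMask, EllipseParams | None]:
    lab = mask.labels
    skin = lab == SKIN
    pupil_region = lab == PUPIL
    ocular_region = pupil_region | (lab == IRIS)
    iris_fit = _fit_region_ellipse(ocular_region, occluder=skin, circular=True)
    if iris_fit is None:
        return mask, None
    fissure = ocular_region | (lab == SCLERA)
    out = lab.copy()
    iris_raster = _raster_ellipse(iris_fit, lab.shape) & fissure
    out[ocular_region & ~iris_raster] = SCLERA
    out[iris_raster] = IRIS
    pupil_fit = _fit_region_ellipse(pupil_region, occluder=skin)
    if pupil_fit is not None:
        pupil_raster = _raster_ellipse(pupil_fit, lab.shape) & iris_raster
        out[pupil_raster] = PUPIL
    elif pupil_region.any():
        out[pupil_region & iris_raster] = PUPIL
    return LabelMask(out), iris_fit


def regularize_mask(mask: LabelMask) -> LabelMask:
    """Replace the segmented pupil and iris with fitted filled ellipses.

    The iris is fitted as a circle to the boundary of the combined
    pupil+iris region (a circle stays well-constrained when the lids leave
    only a partial limbus arc visible) and the pupil as a general ellipse
    to the pupil boundary, in both cases using
    only contour stretches not occluded by the eyelids; the fitted rasters
    are clipped to the original palpebral fissure (the lids keep covering
    whatever they covered) and the pupil additionally to the iris ellipse.
    Former pupil/iris pixels left uncovered become sclera; covered pixels
    are overwritten with priority pupil > iris.  If a region is empty or
    its fit fails, the mask passes through unchanged for that region.
    """
    reg, _ = _regularize(mask)
    return reg


def _fissure(mask: LabelMask) -> np.ndarray:
    lab = mask.labels
    return (lab == PUPIL) | (lab == IRIS) | (lab == SCLERA)


def eyelid_distance(mask: LabelMask) -> tuple[int, int | None]:
    """Palpebral fissure height: max per-column vertical extent of the fissure.

    Returns ``(distance_px, column)``; a closed eye (no fissure pixels)
    returns ``(0, None)``.
    """
    fis = _fissure(mask)
    cols = np.nonzero(fis.any(axis=0))[0]
    if cols.size == 0:
        return 0, None
    rows = np.arange(mask.height)
    first = np.array([rows[fis[:, c]][0] for c in cols])
    last = np.array([rows[fis[:, c]][-1] for c in cols])
    extent = last - first + 1
    k = int(np.argmax(extent))
    return int(extent[k]), int(cols[k])


def clock_point(mask: LabelMask, iris: EllipseParams | None) -> tuple[str, int]:
    """Hour band reached by the upper lid on the iris clock face, with grade.

    The fitted iris is treated as a circle of radius ``r`` (major semi-axis)
    centered at ``(cx, cy)``.  The upper-lid margin height ``h`` is the
    topmost fissure row in the column nearest ``cx``; the relative drop
    ``t = (h - (cy - r)) / (2 r)`` (clamped to [0, 1]) is mapped to hour
    bands through the chord heights of 30-degree hour lines.  A boundary
    value is assigned to the less severe band.  An empty fissure, or a
    missing iris fit, means the eye is fully closed: band "6", grade 4.
    """
    fis = _fissure(mask)
    if iris is None or not fis.any():
        return "6", CLOCK_GRADES["6"]
    cx, cy = iris.center
    r = iris.radius
    cols_with = np.nonzero(fis.any(axis=0))[0]
    col = int(cols_with[np.argmin(np.abs(cols_with - cx))])
    h = int(np.nonzero(fis[:, col])[0][0])
    t = (h - (cy - r)) / (2 * r)
    t = min(max(t, 0.0), 1.0)
    if t >= 1.0:
        band = "6"
    else:
        band = "7-5"
        for threshold, name in _CLOCK_THRESHOLDS:
            if t <= threshold:
                band = name
                break
    return band, CLOCK_GRADES[band]


def scleral_area(
    mask: LabelMask, iris: EllipseParams | None, gaze: str = "front"
) -> tuple[int, int, int, int, float]:
    """Sclera split left/right of the iris center, and the gaze-side proportion.

    Sclera pixels with column index strictly below the iris center x count
    as left, strictly above as right; pixels exactly on the dividing line
    belong to neither side (this keeps the split exactly equivariant under
    horizontal flips).  The gaze side selects which count enters
    the proportion; a ``front`` gaze falls back to the larger side.  The eye
    area is the union of pupil, iris, sclera and caruncle pixels.  Without
    an iris fit the sclera cannot be lateralized and all counts on the
    missing side are 0.

    Returns ``(left_px, right_px, gaze_px, eye_area_px, proportion)``.
    """
    if gaze not in ("left", "right", "front"):
        raise ValueError("gaze must be 'left', 'right' or 'front'")
    lab = mask.labels
    sclera = lab == SCLERA
    eye_area = int((lab != SKIN).sum())
    if iris is None:
        total = int(sclera.sum())
        left, right = total, 0
    else:
        cols = np.nonzero(sclera)[1]
        left = int((cols < iris.center[0]).sum())
        right = int((cols > iris.center[0]).sum())
    gaze_px = {"left": left, "right": right, "front": max(left, right)}[gaze]
    proportion = 0.0 if eye_area == 0 else gaze_px / eye_area
    return left, right, gaze_px, eye_area, proportion


def compute_indicators(mask: LabelMask, gaze: str = "front") -> IndicatorSet:
    """Full indicator pipeline: regularize, fit the iris, measure all three.

    Degenerate masks (closed eye, missing iris) yield the documented
    fallback values rather than raising.
    """
    reg, iris = _regularize(mask)
    dist, _ = eyelid_distance(reg)
    band, grade = clock_point(reg, iris)
    left, right, gaze_px, eye_area, proportion = scleral_area(reg, iris, gaze)
    return IndicatorSet(
        eyelid_distance_px=dist,
        clock_point=band,
        clock_grade=grade,
        sclera_left_px=left,
        sclera_right_px=right,
        sclera_gaze_px=gaze_px,
        eye_area_px=eye_area,
        sclera_proportion=proportion,
    )
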