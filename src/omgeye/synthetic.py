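"""Parametric generator of 5-class eye masks with analytic ground truth.

A synthetic eye is built from simple geometry: the palpebral fissure is
bounded by two parabolic lid arcs whose maximal separation is the
``aperture``; inside the fissure sit the iris disk (shifted from the
fissure center by ``gaze_offset``) and the concentric pupil disk; the
remaining fissure is sclera except for a small caruncle wedge at the nasal
corner; everything outside is skin.  Ptosis is emulated by shrinking the
aperture (the lid arcs then clip the iris), impaired lateral gaze by
leaving the iris near the fissure center while the subject "looks" to the
side.

Ground-truth indicators are derived from the emitted mask by exact pixel
counting against the *true* generating circle — no ellipse fitting — so
recovery tests compare the analysis pipeline against an independent
geometric oracle.  A prediction-corruption model (boundary jitter plus
probability softening) stands in for imperfect network output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import CLOCK_GRADES, _CLOCK_THRESHOLDS
from .losses import boundary_band
from .mask import CARUNCLE, IRIS, PUPIL, SCLERA, SKIN, LabelMask, ProbMap

__all__ = [
    "EyeGeometry",
    "GroundTruthIndicators",
    "CohortSubject",
    "generate_eye",
    "corrupt_prediction",
    "generate_cohort",
]

#: Fissure half-width as a multiple of the iris radius.
FISSURE_HALF_WIDTH_FACTOR = 2.0

#: Caruncle wedge: fissure pixels beyond this |u| on the nasal side.
CARUNCLE_U = 0.85


@dataclass(frozen=True)
class EyeGeometry:
    """Generative parameters of one synthetic eye.

    Distances are in pixels.  ``gaze_offset`` is the signed horizontal shift
    of the iris center from the fissure center (positive = toward the image
    right); ``lid_curvature`` skews how the aperture is split between the
    upper and lower lid arc (1 = symmetric, >1 gives the upper lid a larger
    share).  The fissure half-width is ``2 x iris_radius``.
    """

    width: int = 192
    height: int = 144
    iris_center: tuple[float, float] = (96.0, 72.0)
    iris_radius: float = 32.0
    pupil_radius: float = 12.0
    aperture: float = 52.0
    lid_curvature: float = 1.0
    gaze_offset: float = 0.0
    caruncle_side: str = "left"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pupil_radius >= self.iris_radius:
            raise ValueError("pupil_radius must be smaller than iris_radius")
        if self.pupil_radius <= 0:
            raise ValueError("pupil_radius must be positive")
        if self.aperture < 0:
            raise ValueError("aperture must be >= 0")
        if self.lid_curvature <= 0:
            raise ValueError("lid_curvature must be positive")
        if self.caruncle_side not in ("left", "right"):
            raise ValueError("caruncle_side must be 'left' or 'right'")
        cx, cy = self.iris_center
        r = self.iris_radius
        if not (0 <= cx - r and cx + r < self.width and 0 <= cy - r and cy + r < self.height):
            raise ValueError("iris disk must lie inside the image")

    @property
    def fissure_center(self) -> tuple[float, float]:
        return (self.iris_center[0] - self.gaze_offset, self.iris_center[1])

    @property
    def fissure_half_width(self) -> float:
        return FISSURE_HALF_WIDTH_FACTOR * self.iris_radius


@dataclass(frozen=True)
class GroundTruthIndicators:
    """Indicators computed at generation time from the emitted mask.

    Counts are exact pixel counts; the clock point uses the true generating
    iris circle, so any disagreement with the analysis pipeline is due to
    the pipeline, not rasterization of the reference.
    """

    eyelid_distance_px: int
    sclera_left_px: int
    sclera_right_px: int
    sclera_gaze_px: int
    eye_area_px: int
    sclera_proportion: float
    clock_point: str
    clock_grade: int
    gaze: str


@dataclass(frozen=True)
class CohortSubject:
    """One synthetic subject: a left and a right eye sharing a phenotype."""

    left_mask: LabelMask
    right_mask: LabelMask
    left_truth: GroundTruthIndicators
    right_truth: GroundTruthIndicators
    gaze: str
    label: str  # "normal" or "omg"
    seed: int


def _rasterize(geom: EyeGeometry) -> np.ndarray:
    h, w = geom.height, geom.width
    rows, cols = np.indices((h, w), dtype=float)
    xf, yf = geom.fissure_center
    W = geom.fissure_half_width
    c = geom.lid_curvature
    a_up = geom.aperture * c / (1.0 + c)
    a_lo = geom.aperture / (1.0 + c)
    u = (cols - xf) / W
    shape_fn = np.clip(1.0 - u * u, 0.0, None)
    # lid arcs themselves are lid margin (skin): open-interval membership,
    # so a zero aperture means fully closed lids with no fissure line
    fissure = (np.abs(u) < 1.0) & (rows > yf - a_up * shape_fn) & (rows < yf + a_lo * shape_fn)

    lab = np.full((h, w), SKIN, dtype=np.int64)
    lab[fissure] = SCLERA

    icx, icy = geom.iris_center
    iris_disk = (cols - icx) ** 2 + (rows - icy) ** 2 <= geom.iris_radius**2
    lab[fissure & iris_disk] = IRIS
    pupil_disk = (cols - icx) ** 2 + (rows - icy) ** 2 <= geom.pupil_radius**2
    lab[fissure & iris_disk & pupil_disk] = PUPIL

    nasal_u = -u if geom.caruncle_side == "left" else u
    caruncle = fissure & (nasal_u > CARUNCLE_U) & (lab == SCLERA)
    lab[caruncle] = CARUNCLE
    return lab


def _clock_from_mask(lab: np.ndarray, cx: float, cy: float, r: float) -> tuple[str, int]:
    fissure = (lab == PUPIL) | (lab == IRIS) | (lab == SCLERA)
    cols_with = np.nonzero(fissure.any(axis=0))[0]
    if cols_with.size == 0:
        return "6", CLOCK_GRADES["6"]
    col = int(cols_with[np.argmin(np.abs(cols_with - cx))])
    h = int(np.nonzero(fissure[:, col])[0][0])
    t = min(max((h - (cy - r)) / (2 * r), 0.0), 1.0)
    if t >= 1.0:
        band = "6"
    else:
        band = "7-5"
        for threshold, name in _CLOCK_THRESHOLDS:
            if t <= threshold:
                band = name
                break
    return band, CLOCK_GRADES[band]


def _truth_from_mask(lab: np.ndarray, geom: EyeGeometry, gaze: str) -> GroundTruthIndicators:
    fissure = (lab == PUPIL) | (lab == IRIS) | (lab == SCLERA)
    extents = fissure.sum(axis=0)  # lid arcs are single-valued per column
    eyelid = int(extents.max()) if fissure.any() else 0

    icx = geom.iris_center[0]
    sclera_cols = np.nonzero(lab == SCLERA)[1]
    left = int((sclera_cols < icx).sum())
    right = int((sclera_cols > icx).sum())
    eye_area = int((lab != SKIN).sum())
    gaze_px = {"left": left, "right": right, "front": max(left, right)}[gaze]
    proportion = 0.0 if eye_area == 0 else gaze_px / eye_area

    if fissure.any():
        band, grade = _clock_from_mask(lab, icx, geom.iris_center[1], geom.iris_radius)
    else:
        band, grade = "6", CLOCK_GRADES["6"]
    return GroundTruthIndicators(
        eyelid_distance_px=eyelid,
        sclera_left_px=left,
        sclera_right_px=right,
        sclera_gaze_px=gaze_px,
        eye_area_px=eye_area,
        sclera_proportion=proportion,
        clock_point=band,
        clock_grade=grade,
        gaze=gaze,
    )


def generate_eye(
    geom: EyeGeometry, gaze: str = "front"
) -> tuple[LabelMask, GroundTruthIndicators]:
    """Rasterize one synthetic eye and its analytic ground-truth indicators.

    ``gaze`` selects which side's sclera enters the ground-truth proportion
    (it does not change the mask; the iris position is fully determined by
    ``gaze_offset``).
    """
    if gaze not in ("left", "right", "front"):
        raise ValueError("gaze must be 'left', 'right' or 'front'")
    lab = _rasterize(geom)
    return LabelMask(lab), _truth_from_mask(lab, geom, gaze)


def corrupt_prediction(
    mask: LabelMask, jitter_px: int = 0, softness: float = 0.0, seed: int = 0,
    m: int = 5,
) -> ProbMap:
    """Turn a clean mask into an imperfect probability map.

    Pixels within ``jitter_px`` of a class boundary take the label of a
    uniformly random pixel at most ``jitter_px`` away (emulating boundary
    localization error), then the one-hot encoding is blended with the
    uniform distribution: ``p = (1 - softness) * onehot + softness / m``.
    With ``jitter_px = 0`` and ``softness = 0`` the output is the exact
    one-hot encoding of the input.
    """
    if jitter_px < 0:
        raise ValueError("jitter_px must be >= 0")
    if not 0 <= softness < 1:
        raise ValueError("softness must lie in [0, 1)")
    lab = mask.labels.copy()
    rng = np.random.default_rng(seed)
    if jitter_px > 0:
        band = boundary_band(mask, jitter_px)
        rr, cc = np.nonzero(band)
        dr = rng.integers(-jitter_px, jitter_px + 1, size=rr.size)
        dc = rng.integers(-jitter_px, jitter_px + 1, size=rr.size)
        src_r = np.clip(rr + dr, 0, mask.height - 1)
        src_c = np.clip(cc + dc, 0, mask.width - 1)
        lab[rr, cc] = mask.labels[src_r, src_c]
    probs = np.full((mask.height, mask.width, m), softness / m, dtype=float)
    rows, cols = np.indices(mask.shape)
    probs[rows, cols, lab] += 1.0 - softness
    return ProbMap(probs)


def _sample_base_geometry(rng: np.random.Generator, seed: int) -> EyeGeometry:
    width, height = 192, 144
    iris_radius = float(rng.uniform(28.0, 34.0))
    pupil_radius = float(rng.uniform(0.30, 0.45) * iris_radius)
    aperture = float(rng.uniform(1.25, 1.70) * iris_radius)
    lid_curvature = float(rng.uniform(0.8, 1.25))
    return EyeGeometry(
        width=width,
        height=height,
        iris_center=(width / 2.0, height / 2.0),
        iris_radius=iris_radius,
        pupil_radius=pupil_radius,
        aperture=aperture,
        lid_curvature=lid_curvature,
        gaze_offset=0.0,
        caruncle_side="left",
        seed=seed,
    )


def _offset_for_phenotype(
    base: EyeGeometry, gaze: str, phenotype: str
) -> EyeGeometry | None:
    """Deterministically pick a gaze offset realizing the phenotype.

    A normal eye rotates far toward the gaze side (small residual gaze-side
    sclera, proportion < 0.025); an OMG eye barely moves (proportion
    >= 0.035, i.e. above the 3% rule with margin).  Candidate offsets are
    scanned from the appropriate end; ``None`` if no offset qualifies.
    """
    sign = -1.0 if gaze == "left" else 1.0
    max_mag = 0.95 * base.iris_radius  # iris stays well inside the fissure
    mags = np.linspace(0.0, max_mag, 25)
    candidates = mags[::-1] if phenotype == "normal" else mags
    for mag in candidates:
        cand = replace(base, gaze_offset=float(sign * mag))
        cx = cand.iris_center[0]
        if not (cand.iris_radius <= cx < cand.width - cand.iris_radius):
            continue
        lab = _rasterize(cand)
        truth = _truth_from_mask(lab, cand, gaze)
        if phenotype == "normal" and truth.sclera_proportion < 0.025:
            return cand
        if phenotype == "omg" and truth.sclera_proportion >= 0.035:
            return cand
    return None


def generate_cohort(n: int, phenotype: str, seed: int = 0) -> list[CohortSubject]:
    """Generate ``n`` two-eyed subjects of the given phenotype.

    Normal subjects have gaze-side scleral proportions below 3% in both
    eyes; OMG subjects above 3% with at least a 0.5 percentage-point
    margin.  The cohort is deterministic for a given seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if phenotype not in ("normal", "omg"):
        raise ValueError("phenotype must be 'normal' or 'omg'")
    rng = np.random.default_rng(seed)
    subjects: list[CohortSubject] = []
    attempts = 0
    while len(subjects) < n:
        attempts += 1
        if attempts > 50 * n:
            raise RuntimeError("cohort sampling failed to realize the phenotype")
        subj_seed = int(rng.integers(0, 2**31 - 1))
        subj_rng = np.random.default_rng(subj_seed)
        gaze = "left" if subj_rng.random() < 0.5 else "right"
        eyes = []
        for side in ("left", "right"):
            base = _sample_base_geometry(subj_rng, subj_seed)
            base = replace(base, caruncle_side="right" if side == "left" else "left")
            geom = _offset_for_phenotype(base, gaze, phenotype)
            if geom is None:
                break
            eyes.append(generate_eye(geom, gaze))
        if len(eyes) != 2:
            continue
        (lm, lt), (rm, rt) = eyes
        subjects.append(
            CohortSubject(
                left_mask=lm,
                right_mask=rm,
                left_truth=lt,
                right_truth=rt,
                gaze=gaze,
                label=phenotype,
                seed=subj_seed,
            )
        )
    return subjects
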