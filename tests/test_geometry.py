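"""Ellipse/circle fitting, mask regularization, and the three ocular indicators."""

import math

import numpy as np
import pytest

from omgeye.geometry import (
    CLOCK_GRADES,
    EllipseFitError,
    EllipseParams,
    clock_point,
    compute_indicators,
    eyelid_distance,
    fit_circle,
    fit_ellipse,
    regularize_mask,
    scleral_area,
)
from omgeye.mask import IRIS, PUPIL, SCLERA, LabelMask, hflip
from omgeye.synthetic import EyeGeometry, generate_eye


def ellipse_points(cx, cy, a, b, angle, n=36):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    x = cx + a * np.cos(t) * np.cos(angle) - b * np.sin(t) * np.sin(angle)
    y = cy + a * np.cos(t) * np.sin(angle) + b * np.sin(t) * np.cos(angle)
    return np.column_stack([x, y])


class TestFitEllipse:
    def test_circle_recovered_exactly(self):
        fit = fit_ellipse(ellipse_points(50, 40, 10, 10, 0.0))
        assert fit.center == pytest.approx((50, 40), abs=1e-6)
        assert fit.semi_axes == pytest.approx((10, 10), abs=1e-6)

    def test_rotated_ellipse_recovered(self):
        fit = fit_ellipse(ellipse_points(50, 40, 12, 7, 0.5))
        assert fit.center == pytest.approx((50, 40), abs=1e-6)
        assert fit.semi_axes == pytest.approx((12, 7), abs=1e-6)
        assert fit.angle == pytest.approx(0.5, abs=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(EllipseFitError, match="5 points"):
            fit_ellipse(ellipse_points(0, 0, 5, 3, 0.0, n=4))

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(EllipseFitError):
            fit_ellipse(pts)


class TestFitCircle:
    def test_full_circle_recovered(self):
        fit = fit_circle(ellipse_points(30, 20, 8, 8, 0.0))
        assert fit.center == pytest.approx((30, 20), abs=1e-9)
        assert fit.radius == pytest.approx(8, abs=1e-9)

    def test_partial_arc_recovered(self):
        # 100-degree arc only — the situation of a lid-occluded limbus
        t = np.linspace(-0.9, 0.9, 30)
        pts = np.column_stack([30 + 8 * np.cos(t), 20 + 8 * np.sin(t)])
        fit = fit_circle(pts)
        assert fit.center == pytest.approx((30, 20), abs=1e-6)
        assert fit.radius == pytest.approx(8, abs=1e-6)


def _disk_mask(shape, cx, cy, r_pupil, r_iris, fill=SCLERA):
    rows, cols = np.indices(shape)
    lab = np.full(shape, 0, dtype=int)
    lab[(rows - cy) ** 2 + (cols - cx) ** 2 <= (r_iris + 6) ** 2] = fill
    lab[(rows - cy) ** 2 + (cols - cx) ** 2 <= r_iris**2] = IRIS
    lab[(rows - cy) ** 2 + (cols - cx) ** 2 <= r_pupil**2] = PUPIL
    return LabelMask(lab)


class TestRegularizeMask:
    def test_clean_disks_nearly_unchanged(self):
        # non-integer radii: no pixel centers sit exactly on the circle,
        # so the <= / < rasterization knife-edge cannot bite
        mask = _disk_mask((80, 80), 40, 40, 8.5, 20.5)
        reg = regularize_mask(mask)
        for cls in (PUPIL, IRIS):
            before = int((mask.labels == cls).sum())
            after = int((reg.labels == cls).sum())
            assert abs(after - before) <= 0.02 * before

    def test_rim_noise_removed(self, rng):
        mask = _disk_mask((80, 80), 40, 40, 8, 20)
        noisy = mask.labels.copy()
        # salt noise on the pupil rim: flip ~10% of rim pixels to iris
        rows, cols = np.indices(noisy.shape)
        rim = ((rows - 40) ** 2 + (cols - 40) ** 2 <= 9**2) & (
            (rows - 40) ** 2 + (cols - 40) ** 2 >= 7**2
        )
        flip = rim & (rng.random(noisy.shape) < 0.10)
        noisy[flip & (noisy == PUPIL)] = IRIS
        noisy[flip & (noisy == IRIS)] = PUPIL
        reg = regularize_mask(LabelMask(noisy))
        clean_area = int((mask.labels == PUPIL).sum())
        reg_area = int((reg.labels == PUPIL).sum())
        assert abs(reg_area - clean_area) <= 0.05 * clean_area

    def test_no_ocular_region_passes_through(self):
        mask = LabelMask(np.zeros((10, 10), dtype=int))
        assert regularize_mask(mask) == mask


class TestEyelidDistance:
    def test_closed_eye_is_zero(self):
        dist, col = eyelid_distance(LabelMask(np.zeros((10, 10), dtype=int)))
        assert dist == 0 and col is None

    def test_rectangular_fissure(self):
        lab = np.zeros((20, 20), dtype=int)
        lab[5:15, 3:17] = SCLERA
        dist, col = eyelid_distance(LabelMask(lab))
        assert dist == 10 and 3 <= col <= 16

    def test_generator_aperture_recovered(self):
        geom = EyeGeometry(aperture=40.0)
        mask, truth = generate_eye(geom)
        dist, _ = eyelid_distance(mask)
        assert abs(dist - truth.eyelid_distance_px) <= 1


class TestClockPoint:
    iris = EllipseParams(center=(20.0, 20.0), semi_axes=(10.0, 10.0), angle=0.0)

    def _mask_with_margin(self, h_margin):
        lab = np.zeros((45, 41), dtype=int)
        lab[h_margin:31, :] = SCLERA
        return LabelMask(lab)

    def test_margin_above_iris_top_is_twelve(self):
        band, grade = clock_point(self._mask_with_margin(10), self.iris)
        assert (band, grade) == ("12", 0)

    def test_margin_at_center_boundary_less_severe(self):
        # t = (20 - 10) / 20 = 0.5 exactly -> boundary goes to 10-2 (grade 1)
        band, grade = clock_point(self._mask_with_margin(20), self.iris)
        assert (band, grade) == ("10-2", 1)

    def test_margin_just_below_center_is_nine_three(self):
        band, grade = clock_point(self._mask_with_margin(21), self.iris)
        assert (band, grade) == ("9-3", 2)

    def test_closed_eye_is_six(self):
        band, grade = clock_point(LabelMask(np.zeros((45, 41), dtype=int)), self.iris)
        assert (band, grade) == ("6", 4)

    def test_grade_monotone_in_lid_drop(self):
        grades = [clock_point(self._mask_with_margin(h), self.iris)[1] for h in range(10, 31)]
        assert grades == sorted(grades)


class TestScleralArea:
    def test_no_sclera_means_zero_proportion(self):
        lab = np.zeros((20, 20), dtype=int)
        lab[8:12, 8:12] = IRIS
        iris = EllipseParams(center=(10.0, 10.0), semi_axes=(2.0, 2.0), angle=0.0)
        *_, prop = scleral_area(LabelMask(lab), iris, "left")
        assert prop == 0.0

    def test_constructed_counts(self):
        lab = np.zeros((40, 40), dtype=int)
        lab[0:25, 0:38] = IRIS  # eye area filler: 950 px
        lab[30:35, 0:10] = SCLERA  # 50 px left of center
        iris = EllipseParams(center=(20.0, 12.0), semi_axes=(5.0, 5.0), angle=0.0)
        left, right, gaze_px, area, prop = scleral_area(LabelMask(lab), iris, "left")
        assert (left, right) == (50, 0)
        assert area == 1000
        assert prop == pytest.approx(0.05)

    def test_gaze_side_grows_when_iris_looks_away(self):
        # subject gazes left; the further the iris sits to the right,
        # the more left-side sclera remains exposed
        props = []
        for g in (0.0, 6.0, 12.0, 18.0):
            mask, truth = generate_eye(EyeGeometry(gaze_offset=g), gaze="left")
            props.append(truth.sclera_proportion)
        assert props == sorted(props)
        assert props[-1] > props[0]


class TestComputeIndicators:
    def test_closed_eye_degenerate_values(self):
        ind = compute_indicators(LabelMask(np.zeros((20, 20), dtype=int)))
        assert ind.eyelid_distance_px == 0
        assert (ind.clock_point, ind.clock_grade) == ("6", 4)
        assert ind.sclera_proportion == 0.0

    def test_flip_equivariance(self):
        geom = EyeGeometry(gaze_offset=9.0, caruncle_side="left")
        mask, _ = generate_eye(geom)
        ind = compute_indicators(mask, gaze="left")
        flipped, _ = hflip(mask, "left")
        ind_f = compute_indicators(flipped, gaze="right")
        assert ind_f.eyelid_distance_px == ind.eyelid_distance_px
        assert ind_f.clock_grade == ind.clock_grade
        assert ind_f.sclera_left_px == ind.sclera_right_px
        assert ind_f.sclera_right_px == ind.sclera_left_px
        assert ind_f.sclera_proportion == pytest.approx(ind.sclera_proportion)

    def test_generator_parameters_recovered(self):
        geom = EyeGeometry(aperture=48.0, gaze_offset=-12.0)
        mask, truth = generate_eye(geom, gaze="left")
        ind = compute_indicators(mask, gaze="left")
        assert abs(ind.eyelid_distance_px - truth.eyelid_distance_px) <= 1
        assert abs(ind.sclera_proportion - truth.sclera_proportion) <= 0.01
        assert ind.clock_grade == truth.clock_grade
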