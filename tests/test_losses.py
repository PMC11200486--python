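"""Loss functions against per-pixel loop oracles, closed forms, invariants."""

import math

import numpy as np
import pytest

from omgeye.losses import (
    HybridLossConfig,
    boundary_band,
    boundary_loss,
    boundary_pixels,
    ce_loss,
    dice_loss,
    gamma_schedule,
    hybrid_loss,
    inverse_frequency_weights,
    iou_loss,
    wce_loss,
)
from omgeye.mask import ClassWeights, LabelMask, argmax_mask, one_hot
from conftest import make_random_mask, make_random_probmap

# ---------------------------------------------------------------------------
# Independent loop oracles (pure python, no shared code with the library)


def oracle_ce(pred, gt, weights=None):
    h, w = gt.shape
    m = pred.n_classes
    total = 0.0
    for r in range(h):
        for c in range(w):
            for j in range(m):
                y = 1.0 if gt.labels[r, c] == j else 0.0
                wj = 1.0 if weights is None else weights[j]
                p = min(max(pred.probs[r, c, j], 1e-7), 1.0)
                total += wj * y * math.log(p)
    return -total / (h * w)


def oracle_soft_ratio_loss(pred, gt, dice, pixel_set=None, classes=None):
    m = pred.n_classes
    classes = range(m) if classes is None else classes
    if pixel_set is None:
        pixel_set = [(r, c) for r in range(gt.height) for c in range(gt.width)]
    terms = []
    for j in classes:
        inter = ysum = psum = 0.0
        for r, c in pixel_set:
            y = 1.0 if gt.labels[r, c] == j else 0.0
            p = pred.probs[r, c, j]
            inter += y * p
            ysum += y
            psum += p
        den = (ysum + psum) if dice else (ysum + psum - inter)
        num = 2 * inter if dice else inter
        terms.append(1.0 if den <= 0 else num / den)
    return 1.0 - sum(terms) / len(terms)


def oracle_band(mask, d):
    """Exhaustive pairwise-distance band: min distance to a boundary pixel <= d."""
    h, w = mask.shape
    edges = []
    for r in range(h):
        for c in range(w):
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and mask.labels[rr, cc] != mask.labels[r, c]:
                    edges.append((r, c))
                    break
    band = np.zeros((h, w), dtype=bool)
    for r in range(h):
        for c in range(w):
            band[r, c] = any(math.hypot(r - er, c - ec) <= d for er, ec in edges)
    return band


def oracle_boundary_loss(pred, gt, d):
    band = oracle_band(gt, d) | oracle_band(argmax_mask(pred), d)
    pixel_set = [(r, c) for r in range(gt.height) for c in range(gt.width) if band[r, c]]
    if not pixel_set:
        return 0.0
    classes = [j for j in (1, 2, 3, 4) if j < pred.n_classes]
    return oracle_soft_ratio_loss(pred, gt, dice=False, pixel_set=pixel_set, classes=classes)


# ---------------------------------------------------------------------------


class TestPointwiseLosses:
    def test_ce_zero_at_exact_one_hot(self, rng):
        gt = make_random_mask(rng)
        assert ce_loss(one_hot(gt), gt) == pytest.approx(0.0, abs=1e-6)

    def test_ce_uniform_prediction_is_log_m(self, rng):
        for m in (2, 3, 5):
            gt = make_random_mask(rng, m=m)
            uniform = make_random_probmap(rng, m=m)
            probs = np.full_like(uniform.probs, 1.0 / m)
            from omgeye.mask import ProbMap

            assert ce_loss(ProbMap(probs), gt) == pytest.approx(math.log(m), rel=1e-9)

    def test_ce_matches_loop_oracle(self, rng):
        for _ in range(10):
            m = int(rng.choice([2, 3, 5]))
            gt = make_random_mask(rng, 2, 2, m)
            pred = make_random_probmap(rng, 2, 2, m)
            assert ce_loss(pred, gt) == pytest.approx(oracle_ce(pred, gt), abs=1e-6)

    def test_wce_unit_weights_reduce_to_ce(self, rng):
        gt = make_random_mask(rng)
        pred = make_random_probmap(rng)
        w = ClassWeights(np.ones(5))
        assert wce_loss(pred, gt, w) == pytest.approx(ce_loss(pred, gt), rel=1e-12)

    def test_wce_zero_weight_silences_class(self, rng):
        gt = LabelMask(np.zeros((3, 3), dtype=int))
        pred = make_random_probmap(rng, 3, 3)
        w = ClassWeights(np.array([0.0, 1, 1, 1, 1]))
        assert wce_loss(pred, gt, w) == pytest.approx(0.0, abs=1e-12)

    def test_wce_matches_loop_oracle(self, rng):
        gt = make_random_mask(rng, 2, 2, 2)
        pred = make_random_probmap(rng, 2, 2, 2)
        w = ClassWeights(np.array([1.0, 2.0]))
        assert wce_loss(pred, gt, w) == pytest.approx(
            oracle_ce(pred, gt, weights=[1.0, 2.0]), abs=1e-6
        )

    def test_wce_wrong_length_rejected(self, rng):
        with pytest.raises(ValueError, match="weights"):
            wce_loss(make_random_probmap(rng), make_random_mask(rng), ClassWeights(np.ones(3)))


class TestRegionLosses:
    def test_zero_at_exact_one_hot(self, rng):
        gt = make_random_mask(rng)
        assert iou_loss(one_hot(gt), gt) == pytest.approx(0.0, abs=1e-9)
        assert dice_loss(one_hot(gt), gt) == pytest.approx(0.0, abs=1e-9)

    def test_complement_prediction_scores_one(self):
        gt = LabelMask(np.array([[0, 1], [1, 0]]))
        flipped = LabelMask(1 - gt.labels)
        assert iou_loss(one_hot(flipped, 2), gt) == pytest.approx(1.0)
        assert dice_loss(one_hot(flipped, 2), gt) == pytest.approx(1.0)

    def test_match_loop_oracle_and_dice_le_iou(self, rng):
        for _ in range(25):
            m = int(rng.choice([2, 3, 5]))
            gt = make_random_mask(rng, 4, 4, m)
            pred = make_random_probmap(rng, 4, 4, m)
            li = iou_loss(pred, gt)
            ld = dice_loss(pred, gt)
            assert li == pytest.approx(oracle_soft_ratio_loss(pred, gt, dice=False), abs=1e-6)
            assert ld == pytest.approx(oracle_soft_ratio_loss(pred, gt, dice=True), abs=1e-6)
            assert ld <= li + 1e-12


class TestBoundaryBand:
    def test_uniform_mask_has_empty_band(self):
        mask = LabelMask(np.zeros((6, 6), dtype=int))
        assert not boundary_band(mask, 3).any()
        assert not boundary_pixels(mask).any()

    def test_saturates_to_whole_image(self, rng):
        mask = make_random_mask(rng, 6, 6)
        assert boundary_band(mask, 9).all()  # 9 > diagonal of 6x6

    def test_matches_exhaustive_distance_oracle(self, rng):
        split = LabelMask(np.repeat([[0] * 4 + [1] * 4], 8, axis=0))
        assert (boundary_band(split, 1) == oracle_band(split, 1)).all()
        for _ in range(5):
            mask = make_random_mask(rng, 6, 6, 3)
            for d in (1, 2):
                assert (boundary_band(mask, d) == oracle_band(mask, d)).all()


class TestBoundaryLoss:
    def test_zero_at_exact_one_hot(self, rng):
        gt = make_random_mask(rng)
        assert boundary_loss(one_hot(gt), gt, d=2) == pytest.approx(0.0, abs=1e-9)

    def test_hard_prediction_swap_symmetry(self, rng):
        for _ in range(20):
            g = make_random_mask(rng, 6, 6)
            p = make_random_mask(rng, 6, 6)
            lhs = boundary_loss(one_hot(p), g, d=2)
            rhs = boundary_loss(one_hot(g), p, d=2)
            assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_matches_loop_oracle(self, rng):
        for _ in range(10):
            gt = make_random_mask(rng, 8, 8)
            pred = make_random_probmap(rng, 8, 8)
            assert boundary_loss(pred, gt, d=2) == pytest.approx(
                oracle_boundary_loss(pred, gt, 2), abs=1e-6
            )

    def test_saturated_band_equals_iou_on_ocular_classes(self, rng):
        gt = make_random_mask(rng, 6, 6)
        pred = make_random_probmap(rng, 6, 6)
        big_d = 20
        assert boundary_loss(pred, gt, big_d) == pytest.approx(
            iou_loss(pred, gt, class_set=(1, 2, 3, 4)), abs=1e-12
        )

    def test_uniform_gt_and_pred_give_zero(self):
        gt = LabelMask(np.zeros((5, 5), dtype=int))
        assert boundary_loss(one_hot(gt), gt, d=1) == 0.0


class TestGammaSchedule:
    def test_endpoints(self):
        assert gamma_schedule(0, 150) == 0.0
        assert gamma_schedule(149, 150) == 1.0

    def test_degenerate_single_epoch(self):
        assert gamma_schedule(0, 1, gamma_max=0.7) == 0.7

    def test_midpoint_value(self):
        assert gamma_schedule(75, 150) == pytest.approx(75 / 149)

    def test_out_of_range_epoch_rejected(self):
        with pytest.raises(ValueError):
            gamma_schedule(150, 150)


class TestHybridLoss:
    def test_reduces_to_ce(self, rng):
        gt = make_random_mask(rng)
        pred = make_random_probmap(rng)
        cfg = HybridLossConfig(beta=0.0, local_term="none", gamma_max=0.0)
        assert hybrid_loss(pred, gt, cfg, epoch=0) == pytest.approx(ce_loss(pred, gt))

    def test_additivity_at_final_epoch(self, rng):
        gt = make_random_mask(rng)
        pred = make_random_probmap(rng)
        cfg = HybridLossConfig(local_term="dice", total_epochs=10, d=2)
        expected = ce_loss(pred, gt) + dice_loss(pred, gt) + boundary_loss(pred, gt, 2)
        assert hybrid_loss(pred, gt, cfg, epoch=9) == pytest.approx(expected, rel=1e-12)

    def test_ce_iou_boundary_composition_constructible(self, rng):
        cfg = HybridLossConfig(global_term="ce", local_term="iou", gamma_max=1.0)
        gt = make_random_mask(rng)
        pred = make_random_probmap(rng)
        assert hybrid_loss(pred, gt, cfg, epoch=0) >= 0.0

    def test_local_none_with_positive_beta_rejected(self):
        with pytest.raises(ValueError, match="local"):
            HybridLossConfig(beta=1.0, local_term="none")


class TestInverseFrequencyWeights:
    def test_mean_one_and_inverse_ordering(self, rng):
        gt = LabelMask(np.array([[0, 0, 0, 1]]))
        w = inverse_frequency_weights(gt, m=2)
        assert w.weights.mean() == pytest.approx(1.0)
        assert w.weights[1] > w.weights[0]


def test_all_losses_nonnegative_and_finite(rng):
    for _ in range(20):
        m = int(rng.choice([2, 3, 5]))
        gt = make_random_mask(rng, 5, 5, m)
        pred = make_random_probmap(rng, 5, 5, m)
        values = [
            ce_loss(pred, gt),
            wce_loss(pred, gt, ClassWeights(np.ones(m))),
            iou_loss(pred, gt),
            dice_loss(pred, gt),
            boundary_loss(pred, gt, 1),
        ]
        assert all(np.isfinite(v) and v >= 0 for v in values)
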