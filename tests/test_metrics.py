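"""Pixel, Rand and warping error: hand-worked cases, brute-force oracles,
and topology-preservation properties."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from hlfseg.metrics import (
    _pair_counts,
    evaluate,
    is_simple_point,
    pixel_error,
    rand_error,
    rand_f_score,
    segment_from_membrane,
    warping_error,
)


def brute_force_pair_counts(pred, ref):
    """O(n^2) enumeration over all unordered pixel pairs, excluding
    reference label-0 pixels; prediction label-0 pixels are singletons."""
    pred, ref = np.asarray(pred).ravel(), np.asarray(ref).ravel()
    keep = np.flatnonzero(ref > 0)
    common = in_pred = in_ref = 0
    for a in range(len(keep)):
        for b in range(a + 1, len(keep)):
            i, j = keep[a], keep[b]
            same_pred = pred[i] == pred[j] and pred[i] > 0
            same_ref = ref[i] == ref[j]
            common += same_pred and same_ref
            in_pred += same_pred
            in_ref += same_ref
    return float(common), float(in_pred), float(in_ref)


class TestPixelError:
    def test_perfect_prediction_zero(self):
        gt = np.zeros((8, 8), dtype=np.uint8)
        gt[3, :] = 1
        err, t = pixel_error(gt.astype(float), gt)
        assert err == 0.0 and 0 < t <= 1

    def test_two_by_two_perfect_at_half(self):
        prob = np.array([[0.9, 0.1], [0.8, 0.2]])
        gt = np.array([[1, 0], [1, 0]])
        err, _ = pixel_error(prob, gt)
        assert err == 0.0

    def test_four_pixel_best_f_two_thirds(self):
        # candidates: all-foreground F=2/3 beats the shown split F=1/2
        prob = np.array([[1.0, 1.0], [0.0, 0.0]])
        gt = np.array([[1, 0], [1, 0]])
        err, _ = pixel_error(prob, gt)
        assert err == pytest.approx(1 / 3)

    def test_empty_gt_rejected(self):
        with pytest.raises(ValueError):
            pixel_error(np.zeros((4, 4)), np.zeros((4, 4), dtype=np.uint8))


class TestSegmentFromMembrane:
    def test_no_membrane_single_region(self):
        labels = segment_from_membrane(np.zeros((8, 8), dtype=np.uint8))
        assert np.all(labels == 1)

    def test_vertical_line_two_regions(self):
        binary = np.zeros((8, 8), dtype=np.uint8)
        binary[:, 4] = 1
        labels = segment_from_membrane(binary)
        assert labels.max() == 2
        assert np.all(labels[:, 4] == 0)

    def test_gap_leaks_into_one_region(self):
        binary = np.zeros((8, 8), dtype=np.uint8)
        binary[:, 4] = 1
        binary[3, 4] = 0  # 1-px hole
        labels = segment_from_membrane(binary)
        assert labels.max() == 1


class TestRandError:
    def test_identical_inputs_zero(self):
        gt = np.zeros((16, 16), dtype=np.uint8)
        gt[8, :] = 1
        gt[:, 8] = 1
        err, _ = rand_error(gt.astype(float), gt)
        assert err == 0.0

    def test_hand_case_fully_split(self):
        a = np.array([1, 1, 2, 2])
        b = np.array([1, 2, 1, 2])
        assert rand_f_score(a, b) == 0.0

    def test_hand_case_half(self):
        a = np.array([1, 1, 1, 1])
        b = np.array([1, 1, 2, 2])
        # common=2, P=2/6, R=2/2 -> F=1/2
        assert rand_f_score(a, b) == pytest.approx(0.5)

    def test_pair_counts_match_brute_force(self, rng):
        """Exact agreement with O(n^2) pair enumeration on 50 random
        labelings of <= 64 pixels, zeros included."""
        for _ in range(50):
            h, w = rng.integers(2, 9, 2)
            pred = rng.integers(0, 4, (h, w))
            ref = rng.integers(0, 4, (h, w))
            assert _pair_counts(pred, ref) == brute_force_pair_counts(pred, ref)

    def test_single_region_gt_degenerate(self):
        gt = np.zeros((6, 6), dtype=np.uint8)  # no membrane: one region
        prob = np.zeros((6, 6))
        err, _ = rand_error(prob, gt)
        assert err == 0.0


class TestSimplePoint:
    def test_isolated_center_not_simple(self):
        patch = np.zeros((3, 3), dtype=bool)
        patch[1, 1] = True
        assert not is_simple_point(patch, 4)
        assert not is_simple_point(patch, 8)

    def test_half_plane_edge_simple(self):
        patch = np.zeros((3, 3), dtype=bool)
        patch[:2, :] = True  # center on the straight edge of a half-plane
        assert is_simple_point(patch, 4)

    def test_line_interior_not_simple(self):
        patch = np.zeros((3, 3), dtype=bool)
        patch[1, :] = True  # 4-connected 1-px line through the center
        assert not is_simple_point(patch, 4)

    def test_definition_agrees_with_lut(self, rng):
        """On fully interior patches the ternary lookup table must reproduce
        the direct component-count definition."""
        from hlfseg.metrics import _POW3, _simple_lut

        for conn in (4, 8):
            lut = _simple_lut(conn)
            for _ in range(100):
                bits = rng.integers(0, 2, 9)
                code = int((bits * _POW3).sum())
                assert lut[code] == is_simple_point(bits.reshape(3, 3), conn)


class TestWarpingError:
    def test_identical_zero(self):
        gt = np.zeros((16, 16), dtype=np.uint8)
        gt[8, :] = 1
        assert warping_error(gt, gt) == 0.0

    def test_shifted_line_warped_away(self):
        gt = np.zeros((16, 16), dtype=np.uint8)
        gt[8, :] = 1
        pred = np.zeros((16, 16), dtype=np.uint8)
        pred[9, :] = 1  # pure 1-px boundary shift within tolerance
        assert warping_error(gt, pred, tolerance_px=2.0) == 0.0

    def test_gap_is_topological_and_unfixable(self):
        gt = np.zeros((16, 16), dtype=np.uint8)
        gt[8, :] = 1
        pred = gt.copy()
        pred[8, 5:8] = 0  # break the line
        err = warping_error(gt, pred, tolerance_px=2.0)
        assert err > 0.0
        # closing the gap would merge the two background components: the
        # residual is at most the gap size
        assert err <= 3 / gt.size

    def test_bounded_by_disagreement_and_topology_preserved(self, rng):
        struct4 = ndi.generate_binary_structure(2, 1)
        struct8 = ndi.generate_binary_structure(2, 2)
        for _ in range(50):
            gt = rng.random((12, 12)) < 0.4
            pred = gt ^ (rng.random((12, 12)) < 0.1)
            err, warped = warping_error(gt, pred, return_warped=True)
            assert err <= (gt != pred).mean() + 1e-12
            # fg (4-conn) and bg (8-conn) component counts are invariant
            assert ndi.label(warped, struct4)[1] == ndi.label(gt, struct4)[1]
            assert ndi.label(~warped, struct8)[1] == ndi.label(~gt, struct8)[1]


def test_evaluate_reports_all_metrics(small_image):
    _, gt = small_image
    prob = gt.astype(float) * 0.9 + 0.05
    rep = evaluate(prob, gt, thresholds=np.linspace(0, 1, 16))
    assert rep.pixel_error == 0.0
    assert rep.rand_error == 0.0
    assert rep.warping_error == 0.0
    assert 0 < rep.best_threshold_pixel <= 1
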