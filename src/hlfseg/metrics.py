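"""Segmentation error metrics: pixel error, Rand error, warping error.

These are the three metrics of the 2-D EM membrane-segmentation challenge
convention.  Pixel error is 1 minus the best F-score of per-pixel membrane
agreement over a probability-threshold sweep.  Rand error compares the
region partitions induced by the membrane maps: non-membrane pixels are
grouped into 4-connected regions, and over all unordered pixel pairs the
co-clustering precision/recall give an F-score; Rand error is 1 minus its
maximum over the sweep.  Warping error measures purely topological
disagreement: the ground truth is deformed toward the prediction by flipping
only *simple* pixels (flips that change neither foreground nor background
connectivity) within a small geometric tolerance of the original boundary,
and the disagreement that remains — breaks, mergers, holes — is counted.

Conventions (documented reconstructions of the challenge's):
- membrane = 1 in binary maps; regions are 4-connected non-membrane pixels;
- Rand pair counting excludes pixels labeled 0 (membrane) in either
  segmentation (foreground-restricted);
- warping deforms ground truth toward the prediction, tolerance 2 px,
  foreground connectivity 4 (membrane) and background 8.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

DEFAULT_THRESHOLDS = np.arange(256) / 255.0

_STRUCT4 = ndi.generate_binary_structure(2, 1)
_STRUCT8 = ndi.generate_binary_structure(2, 2)


@dataclass(frozen=True)
class MetricReport:
    pixel_error: float
    rand_error: float
    warping_error: float
    best_threshold_pixel: float
    best_threshold_rand: float


# ---------------------------------------------------------------- pixel error


def _f_score(tp: float, fp: float, fn: float) -> float:
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom > 0 else 0.0


def pixel_error(
    prob: np.ndarray, gt: np.ndarray, thresholds: np.ndarray = DEFAULT_THRESHOLDS
) -> tuple[float, float]:
    """1 - max F-score of the membrane class over a threshold sweep."""
    prob = np.asarray(prob, dtype=np.float64)
    gt = np.asarray(gt).astype(bool)
    if prob.shape != gt.shape:
        raise ValueError("probability map and ground truth shapes differ")
    if not gt.any():
        raise ValueError("ground truth contains no membrane pixels; F undefined")
    n_pos = int(gt.sum())
    best_f, best_t = -1.0, 0.0
    for t in thresholds:
        pred = prob >= t
        tp = int((pred & gt).sum())
        fp = int(pred.sum()) - tp
        fn = n_pos - tp
        f = _f_score(tp, fp, fn)
        if f > best_f:
            best_f, best_t = f, float(t)
    return 1.0 - best_f, best_t


# ----------------------------------------------------------------- Rand error


def segment_from_membrane(binary: np.ndarray) -> np.ndarray:
    """Region labeling induced by a binary membrane map: 4-connected
    components of the non-membrane pixels get labels 1..M, membrane pixels
    get label 0 (excluded from pair counting)."""
    binary = np.asarray(binary).astype(bool)
    labels, _ = ndi.label(~binary, structure=_STRUCT4)
    return labels


def _pair_counts(pred: np.ndarray, ref: np.ndarray) -> tuple[float, float, float]:
    """(pairs co-clustered in both, in prediction, in reference).

    Foreground-restricted: pixels labeled 0 in the *reference* (its membrane)
    are excluded entirely; retained prediction-0 pixels stay in the counts
    but are never co-clustered with anything (each is its own singleton)."""
    pred = np.asarray(pred).ravel()
    ref = np.asarray(ref).ravel()
    keep = ref > 0
    pred, ref = pred[keep], ref[keep]
    if pred.size == 0:
        return 0.0, 0.0, 0.0
    _, ri = np.unique(ref, return_inverse=True)
    n_ref = np.bincount(ri).astype(np.float64)

    grouped = pred > 0
    _, pi = np.unique(pred[grouped], return_inverse=True) if grouped.any() else (
        None,
        np.empty(0, dtype=np.int64),
    )
    n_pred = np.bincount(pi).astype(np.float64)
    nr = int(ri.max()) + 1
    joint = np.bincount(pi * nr + ri[grouped]).astype(np.float64)

    def pairs(x):
        return float((x * (x - 1) / 2).sum())

    return pairs(joint), pairs(n_pred), pairs(n_ref)


def rand_f_score(pred_seg: np.ndarray, ref_seg: np.ndarray) -> float:
    """F-score of pair-based co-clustering precision/recall; ``pred_seg`` is
    the prediction labeling, ``ref_seg`` the reference (ground truth)."""
    common, in_pred, in_ref = _pair_counts(pred_seg, ref_seg)
    if in_pred == 0 and in_ref == 0:
        return 1.0  # degenerate: nothing is co-clustered anywhere
    if in_pred == 0 or in_ref == 0:
        return 0.0
    precision = common / in_pred
    recall = common / in_ref
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def rand_error(
    prob: np.ndarray, gt: np.ndarray, thresholds: np.ndarray = DEFAULT_THRESHOLDS
) -> tuple[float, float]:
    """1 - max Rand F-score over a threshold sweep of the probability map."""
    prob = np.asarray(prob, dtype=np.float64)
    gt_seg = segment_from_membrane(np.asarray(gt).astype(bool))
    best_f, best_t = -1.0, 0.0
    for t in thresholds:
        pred_seg = segment_from_membrane(prob >= t)
        f = rand_f_score(pred_seg, gt_seg)
        if f > best_f:
            best_f, best_t = f, float(t)
    return 1.0 - best_f, best_t


# -------------------------------------------------------------- warping error


def _patch_components(patch: np.ndarray, struct: np.ndarray) -> int:
    return ndi.label(patch, structure=struct)[1]


def is_simple_point(patch: np.ndarray, fg_connectivity: int = 4) -> bool:
    """Whether flipping the center of a 3x3 binary patch preserves both the
    foreground component count (under ``fg_connectivity``) and the background
    component count (under the complementary connectivity) within the patch."""
    patch = np.asarray(patch).astype(bool)
    if patch.shape != (3, 3):
        raise ValueError("patch must be 3x3")
    if fg_connectivity == 4:
        fg_s, bg_s = _STRUCT4, _STRUCT8
    elif fg_connectivity == 8:
        fg_s, bg_s = _STRUCT8, _STRUCT4
    else:
        raise ValueError("fg_connectivity must be 4 or 8")
    flipped = patch.copy()
    flipped[1, 1] = ~flipped[1, 1]
    return (
        _patch_components(patch, fg_s) == _patch_components(flipped, fg_s)
        and _patch_components(~patch, bg_s) == _patch_components(~flipped, bg_s)
    )


_NEIGHBORS4 = ((-1, 0), (1, 0), (0, -1), (0, 1))
_NEIGHBORS8 = _NEIGHBORS4 + ((-1, -1), (-1, 1), (1, -1), (1, 1))


def _count_patch_components(states: list[int], target: int, conn: int) -> int:
    """Connected components of cells with ``states[i] == target`` on the 3x3
    grid; out-of-image cells (state 2) belong to neither class."""
    offsets = _NEIGHBORS4 if conn == 4 else _NEIGHBORS8
    seen = [False] * 9
    count = 0
    for start in range(9):
        if states[start] != target or seen[start]:
            continue
        count += 1
        queue = [start]
        seen[start] = True
        while queue:
            cell = queue.pop()
            r, c = divmod(cell, 3)
            for dr, dc in offsets:
                rr, cc = r + dr, c + dc
                if 0 <= rr < 3 and 0 <= cc < 3:
                    nb = rr * 3 + cc
                    if states[nb] == target and not seen[nb]:
                        seen[nb] = True
                        queue.append(nb)
    return count


_SIMPLE_LUT: dict[int, np.ndarray] = {}
_POW3 = 3 ** np.arange(9)


def _simple_lut(fg_connectivity: int) -> np.ndarray:
    """Simple-point status for all 3^9 ternary 3x3 configurations, cell
    states being 0 = background, 1 = foreground, 2 = outside the image.
    Outside cells join neither class, so border pixels are judged on the
    clipped patch rather than on phantom background."""
    if fg_connectivity not in _SIMPLE_LUT:
        bg_conn = 8 if fg_connectivity == 4 else 4
        lut = np.zeros(3**9, dtype=bool)
        for code in range(3**9):
            states = [(code // p) % 3 for p in _POW3]
            center = states[4]
            if center == 2:
                continue
            flipped = list(states)
            flipped[4] = 1 - center
            lut[code] = (
                _count_patch_components(states, 1, fg_connectivity)
                == _count_patch_components(flipped, 1, fg_connectivity)
                and _count_patch_components(states, 0, bg_conn)
                == _count_patch_components(flipped, 0, bg_conn)
            )
        _SIMPLE_LUT[fg_connectivity] = lut
    return _SIMPLE_LUT[fg_connectivity]


def _patch_code(states: np.ndarray, r: int, c: int) -> int:
    # r, c index the padded state array; weights are row-major over the patch
    patch = states[r - 1 : r + 2, c - 1 : c + 2]
    return int((patch.ravel() * _POW3).sum())


def warping_error(
    gt: np.ndarray,
    pred: np.ndarray,
    tolerance_px: float = 2.0,
    fg_connectivity: int = 4,
    return_warped: bool = False,
):
    """Fraction of pixels still disagreeing after warping ``gt`` toward
    ``pred`` by topology-preserving simple-point flips.

    A pixel may flip if it disagrees with the prediction, is a simple point
    of the current warped ground truth, and lies within ``tolerance_px``
    (Euclidean) of the original ground-truth boundary.  Flips are applied
    greedily in row-major order (each flip removes one disagreement) until
    no legal flip remains; the remaining disagreement fraction is returned.
    """
    gt = np.asarray(gt).astype(bool)
    pred = np.asarray(pred).astype(bool)
    if gt.shape != pred.shape:
        raise ValueError("shapes differ")
    h, w = gt.shape
    n = gt.size

    # pixels within tolerance of the original gt boundary (membrane edge)
    boundary = gt ^ ndi.binary_erosion(gt, structure=_STRUCT4, border_value=1)
    boundary |= gt ^ ndi.binary_dilation(gt, structure=_STRUCT4)
    if boundary.any():
        near = ndi.distance_transform_edt(~boundary) <= tolerance_px
    else:
        near = np.zeros_like(gt)

    lut = _simple_lut(fg_connectivity)
    warped = np.pad(gt, 1, constant_values=False)
    pred_p = np.pad(pred, 1, constant_values=False)
    near_p = np.pad(near, 1, constant_values=False)
    # ternary state view: 0/1 inside the image, 2 on the pad ring
    states = np.full((h + 2, w + 2), 2, dtype=np.int64)
    states[1:-1, 1:-1] = gt.astype(np.int64)

    # candidate heap keyed by row-major index; entries validated lazily
    heap = list(
        np.flatnonzero((warped != pred_p)[1:-1, 1:-1].ravel() & near.ravel())
    )
    heapq.heapify(heap)
    while heap:
        idx = heapq.heappop(heap)
        r, c = divmod(int(idx), w)
        rp, cp = r + 1, c + 1
        if warped[rp, cp] == pred_p[rp, cp] or not near_p[rp, cp]:
            continue
        if not lut[_patch_code(states, rp, cp)]:
            continue
        warped[rp, cp] = ~warped[rp, cp]
        states[rp, cp] = int(warped[rp, cp])
        # a flip can make stalled neighbors (and itself, it now agrees)
        # flippable again; re-queue disagreeing near-boundary neighbors
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr, cc = rp + dr, cp + dc
                if 1 <= rr <= h and 1 <= cc <= w:
                    if warped[rr, cc] != pred_p[rr, cc] and near_p[rr, cc]:
                        heapq.heappush(heap, (rr - 1) * w + (cc - 1))

    error = float((warped[1:-1, 1:-1] != pred).sum()) / n
    if return_warped:
        return error, warped[1:-1, 1:-1]
    return error


# ----------------------------------------------------------------- aggregate


def evaluate(
    prob: np.ndarray,
    gt: np.ndarray,
    thresholds: np.ndarray = DEFAULT_THRESHOLDS,
    tolerance_px: float = 2.0,
) -> MetricReport:
    """All three metrics for one probability map against ground truth.

    Pixel and Rand error share the threshold sweep; warping error consumes
    the binary map at the pixel-error-optimal threshold."""
    p_err, p_t = pixel_error(prob, gt, thresholds)
    r_err, r_t = rand_error(prob, gt, thresholds)
    w_err = warping_error(gt, np.asarray(prob) >= p_t, tolerance_px=tolerance_px)
    return MetricReport(
        pixel_error=p_err,
        rand_error=r_err,
        warping_error=w_err,
        best_threshold_pixel=p_t,
        best_threshold_rand=r_t,
    )
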