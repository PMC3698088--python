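"""The 34-channel low-level (pixel) feature bank.

Membranes in EM sections are thin, dark, elongated ridges; the bank mixes
smoothers that capture local brightness at several scales, derivative filters
that respond to edges and ridges, and two non-local descriptors (ray
features and a Radon-like feature) that capture the geometry of the nearest
boundaries around each pixel.

Canonical channel order (frozen; sample vectors are meaningless without it):

  1-6    3x3 mean, median, maximum, minimum, variance, Gaussian blur (sigma 1)
  7-12   Gaussian blur, sigma in {1.5, 2.0, 3.5, 4.0, 5.0, 6.0}
  13     Sobel gradient magnitude (3x3 kernels)
  14-15  largest / smallest Hessian eigenvalue (sigma 1)
  16     difference of Gaussians (sigma 1 minus sigma 2)
  17     Kuwahara (classical 4-quadrant, 5x5)
  18     Laplacian (3x3)
  19-20  largest / smallest structure-tensor eigenvalue
  21     Gaussian derivative: first-order gradient magnitude (sigma 1)
  22-33  12 ray features: 4 directions (E, S, W, N) x 3 descriptors
         (distance to first edge, gradient magnitude at the hit, cosine of
         the angle between ray and gradient at the hit)
  34     Radon-like feature (edge-segment mean intensity, averaged over
         4 scan directions)

All filters use reflective boundary handling.  After computation each
channel is min-max normalized to [0, 1] over the image (a constant channel
maps to all zeros); ``normalize=False`` returns raw responses.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage import feature as skfeat

RAY_DIRECTIONS = ((0.0, 1.0), (1.0, 0.0), (0.0, -1.0), (-1.0, 0.0))
RAY_DIRECTION_NAMES = ("e", "s", "w", "n")
RAY_CAP_LENGTH = 64

CHANNEL_NAMES: tuple[str, ...] = (
    "mean3",
    "median3",
    "max3",
    "min3",
    "variance3",
    "gauss1.0",
    "gauss1.5",
    "gauss2.0",
    "gauss3.5",
    "gauss4.0",
    "gauss5.0",
    "gauss6.0",
    "sobel",
    "hessian_max",
    "hessian_min",
    "dog",
    "kuwahara",
    "laplacian",
    "structure_max",
    "structure_min",
    "derivative",
    *(
        f"ray_{d}_{kind}"
        for d in RAY_DIRECTION_NAMES
        for kind in ("dist", "grad", "cos")
    ),
    "radon_like",
)

N_CHANNELS = len(CHANNEL_NAMES)  # 34


def _sobel_components(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    gy = ndi.sobel(img, axis=0, mode="reflect")
    gx = ndi.sobel(img, axis=1, mode="reflect")
    return gy, gx


def sobel_magnitude(img: np.ndarray) -> np.ndarray:
    gy, gx = _sobel_components(img)
    return np.hypot(gy, gx)


def _kuwahara(img: np.ndarray) -> np.ndarray:
    """Classical 5x5 Kuwahara: mean of the lowest-variance 3x3 quadrant.

    The four quadrants are the 3x3 corner subwindows of the 5x5 neighborhood;
    on ties the first quadrant in (NW, NE, SW, SE) order wins.
    """
    m = ndi.uniform_filter(img, 3, mode="reflect")
    m2 = ndi.uniform_filter(img * img, 3, mode="reflect")
    v = np.maximum(m2 - m * m, 0.0)
    mp = np.pad(m, 1, mode="reflect")
    vp = np.pad(v, 1, mode="reflect")
    h, w = img.shape
    shifts = ((0, 0), (0, 2), (2, 0), (2, 2))  # NW, NE, SW, SE quadrant centers
    means = np.stack([mp[r : r + h, c : c + w] for r, c in shifts])
    variances = np.stack([vp[r : r + h, c : c + w] for r, c in shifts])
    choice = np.argmin(variances, axis=0)
    return np.take_along_axis(means, choice[None], axis=0)[0]


def edge_map(
    img: np.ndarray,
    sigma: float = 1.0,
    low_threshold: float = 0.1,
    high_threshold: float = 0.2,
) -> np.ndarray:
    """Canny edge map used by the ray and Radon-like features."""
    return skfeat.canny(
        np.asarray(img, dtype=np.float64),
        sigma=sigma,
        low_threshold=low_threshold,
        high_threshold=high_threshold,
    )


def _directional_hits(edges: np.ndarray, direction: tuple[float, float]) -> np.ndarray:
    """Index (along the ray axis) of the first edge pixel at or beyond each
    pixel in the given axis direction; -1 where there is none."""
    h, w = edges.shape
    dy, dx = direction
    if dx != 0:  # horizontal ray
        idx = np.broadcast_to(np.arange(w), (h, w))
        axis, forward = 1, dx > 0
    else:
        idx = np.broadcast_to(np.arange(h)[:, None], (h, w))
        axis, forward = 0, dy > 0
    if forward:
        marked = np.where(edges, idx, np.iinfo(np.int64).max)
        flipped = np.flip(marked, axis=axis)
        hit = np.flip(np.minimum.accumulate(flipped, axis=axis), axis=axis)
        hit = np.where(hit == np.iinfo(np.int64).max, -1, hit)
    else:
        marked = np.where(edges, idx, -1)
        hit = np.maximum.accumulate(marked, axis=axis)
    return hit


def ray_features(
    img: np.ndarray,
    edges: np.ndarray | None = None,
    cap_length: int = RAY_CAP_LENGTH,
) -> np.ndarray:
    """12 ray channels: for each axis direction (E, S, W, N), cast a ray from
    every pixel until the first edge pixel and record (distance, gradient
    magnitude at the hit, cosine between ray and gradient directions).

    A ray that finds no edge within ``cap_length`` (or before the border)
    reports distance ``cap_length`` and zero for the other two descriptors;
    an empty edge map therefore yields all-``cap_length`` distance channels.
    """
    img = np.asarray(img, dtype=np.float64)
    if edges is None:
        edges = edge_map(img)
    if edges.shape != img.shape:
        raise ValueError("edge map shape must match the image")
    gy, gx = _sobel_components(img)
    gmag = np.hypot(gy, gx)
    with np.errstate(invalid="ignore", divide="ignore"):
        gy_u = np.where(gmag > 0, gy / gmag, 0.0)
        gx_u = np.where(gmag > 0, gx / gmag, 0.0)

    h, w = img.shape
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    out = np.empty((12, h, w), dtype=np.float64)
    for k, (dy, dx) in enumerate(RAY_DIRECTIONS):
        hit = _directional_hits(edges, (dy, dx))
        here = cols if dx != 0 else rows
        dist = np.where(hit >= 0, np.abs(hit - here), cap_length)
        found = (hit >= 0) & (dist <= cap_length)
        dist = np.minimum(dist, cap_length).astype(np.float64)
        if dx != 0:
            hit_r = np.broadcast_to(rows, (h, w))
            hit_c = np.where(found, hit, 0)
        else:
            hit_r = np.where(found, hit, 0)
            hit_c = np.broadcast_to(cols, (h, w))
        b = np.where(found, gmag[hit_r, hit_c], 0.0)
        cosang = dy * gy_u[hit_r, hit_c] + dx * gx_u[hit_r, hit_c]
        c = np.where(found, cosang, 0.0)
        out[3 * k] = dist
        out[3 * k + 1] = b
        out[3 * k + 2] = c
    return out


def _segment_means_lines(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Per-pixel mean of its edge-delimited segment, lines along axis 1."""
    h, w = values.shape
    seg = np.cumsum(edges, axis=1)
    global_id = seg + (np.arange(h) * (w + 1))[:, None]
    sums = np.bincount(global_id.ravel(), weights=values.ravel())
    counts = np.bincount(global_id.ravel())
    means = sums / np.maximum(counts, 1)
    return means[global_id]


def radon_like_feature(img: np.ndarray, edges: np.ndarray | None = None) -> np.ndarray:
    """Radon-like channel: along scanlines in 4 directions (0, 45, 90, 135
    degrees), split each line at Canny edge crossings and assign every pixel
    the mean image intensity of its segment; average the 4 direction maps.

    On membrane images this pools the dark membrane intensity along the
    membrane while cell interiors pool their bright cytoplasm, enhancing the
    membrane/interior contrast beyond single-pixel intensity."""
    img = np.asarray(img, dtype=np.float64)
    if edges is None:
        edges = edge_map(img)
    h, w = img.shape
    acc = np.zeros((h, w), dtype=np.float64)

    acc += _segment_means_lines(img, edges)  # 0 deg (rows)
    acc += _segment_means_lines(img.T, edges.T).T  # 90 deg (columns)

    for flip in (False, True):  # 45 and 135 deg (diagonals)
        vals = np.fliplr(img) if flip else img
        eds = np.fliplr(edges) if flip else edges
        out = np.empty((h, w), dtype=np.float64)
        for off in range(-h + 1, w):
            line_v = np.diagonal(vals, offset=off)
            line_e = np.diagonal(eds, offset=off)
            seg = np.cumsum(line_e)
            sums = np.bincount(seg, weights=line_v)
            counts = np.bincount(seg)
            means = sums / counts
            rr = np.arange(max(-off, 0), max(-off, 0) + line_v.size)
            cc = rr + off
            out[rr, cc] = means[seg]
        acc += np.fliplr(out) if flip else out
    return acc / 4.0


def compute_pixel_features(
    img: np.ndarray, normalize: bool = True
) -> np.ndarray:
    """Compute the 34-channel feature stack for a grayscale image.

    Returns an array of shape (34, H, W) in the canonical channel order.
    With ``normalize=True`` each channel is min-max scaled to [0, 1] over the
    image (constant channels become zeros).
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if min(img.shape) < 5:
        raise ValueError(
            f"image {img.shape} is smaller than the largest filter kernel (5x5)"
        )
    h, w = img.shape
    ch = np.empty((N_CHANNELS, h, w), dtype=np.float64)

    ch[0] = ndi.uniform_filter(img, 3, mode="reflect")
    ch[1] = ndi.median_filter(img, 3, mode="reflect")
    ch[2] = ndi.maximum_filter(img, 3, mode="reflect")
    ch[3] = ndi.minimum_filter(img, 3, mode="reflect")
    m2 = ndi.uniform_filter(img * img, 3, mode="reflect")
    ch[4] = np.maximum(m2 - ch[0] * ch[0], 0.0)
    for i, sigma in enumerate((1.0, 1.5, 2.0, 3.5, 4.0, 5.0, 6.0)):
        ch[5 + i] = ndi.gaussian_filter(img, sigma, mode="reflect")
    ch[12] = sobel_magnitude(img)

    Hrr, Hrc, Hcc = skfeat.hessian_matrix(
        img, sigma=1.0, mode="reflect", order="rc", use_gaussian_derivatives=True
    )
    hess = skfeat.hessian_matrix_eigvals([Hrr, Hrc, Hcc])
    ch[13], ch[14] = hess[0], hess[1]  # sorted descending

    ch[15] = ch[5] - ndi.gaussian_filter(img, 2.0, mode="reflect")
    ch[16] = _kuwahara(img)
    ch[17] = ndi.laplace(img, mode="reflect")

    # derivative scale 1, integration scale 3
    smoothed = ndi.gaussian_filter(img, 1.0, mode="reflect")
    A = skfeat.structure_tensor(smoothed, sigma=3.0, mode="reflect", order="rc")
    st = skfeat.structure_tensor_eigenvalues(A)
    ch[18], ch[19] = st[0], st[1]

    ch[20] = ndi.gaussian_gradient_magnitude(img, sigma=1.0, mode="reflect")

    edges = edge_map(img)
    ch[21:33] = ray_features(img, edges)
    ch[33] = radon_like_feature(img, edges)

    if normalize:
        lo = ch.reshape(N_CHANNELS, -1).min(axis=1)[:, None, None]
        hi = ch.reshape(N_CHANNELS, -1).max(axis=1)[:, None, None]
        span = hi - lo
        span[span == 0] = 1.0
        ch = (ch - lo) / span
    return ch
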