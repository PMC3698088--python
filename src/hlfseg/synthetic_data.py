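"""Seeded generator of EM-like test images with exact membrane ground truth.

Real serial-section TEM images of neural tissue show bright, textured cell
interiors separated by thin dark membranes, with occasional dark organelles
(mitochondria, vesicles) inside the cells.  This module emulates that
appearance on a pixel grid so that every downstream stage — oversegmentation,
feature extraction, classification, postprocessing and the evaluation
metrics — can be exercised with a known, exact membrane mask and no external
data.

Construction: random cell seed points -> Voronoi tessellation of the pixel
grid -> Voronoi edges dilated to the requested membrane width give the binary
ground truth; the image is cytoplasm intensity plus a per-cell Gaussian
texture field, membrane intensity on the mask, optional darker elliptical
organelles inside cells, followed by Gaussian blur and additive Gaussian
noise, clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage as ndi


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic EM section.

    Intensities are in [0, 1]; membranes must be darker than cytoplasm,
    matching EM appearance where membranes stain dark.
    """

    height: int = 256
    width: int = 256
    n_cells: int = 12
    membrane_width: int = 3
    cytoplasm_mean: float = 0.7
    membrane_mean: float = 0.15
    texture_sd: float = 0.05
    noise_sd: float = 0.03
    blur_sigma: float = 1.0
    organelle_density: float = 0.5
    organelle_mean: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError(
                f"image dimensions must be positive, got {self.height}x{self.width}"
            )
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.n_cells > self.height * self.width:
            raise ValueError(
                f"n_cells={self.n_cells} exceeds the number of pixels "
                f"({self.height * self.width})"
            )
        if self.membrane_width < 1:
            raise ValueError("membrane_width must be >= 1")
        if not (self.membrane_mean < self.cytoplasm_mean):
            raise ValueError("membranes must be darker than cytoplasm")


def _voronoi_labels(shape: tuple[int, int], seeds: np.ndarray) -> np.ndarray:
    """Nearest-seed (Voronoi) cell label for every pixel, ties to lowest id."""
    rows, cols = np.indices(shape)
    # squared Euclidean distance to every seed; argmin takes the lowest id on ties
    d2 = (
        (rows[..., None] - seeds[:, 0][None, None, :]) ** 2
        + (cols[..., None] - seeds[:, 1][None, None, :]) ** 2
    )
    return np.argmin(d2, axis=-1)


def _voronoi_edge_mask(cells: np.ndarray) -> np.ndarray:
    """Pixels whose 4-neighborhood spans >= 2 distinct Voronoi cells."""
    edge = np.zeros(cells.shape, dtype=bool)
    edge[:-1, :] |= cells[:-1, :] != cells[1:, :]
    edge[1:, :] |= cells[1:, :] != cells[:-1, :]
    edge[:, :-1] |= cells[:, :-1] != cells[:, 1:]
    edge[:, 1:] |= cells[:, 1:] != cells[:, :-1]
    return edge


def _disk(radius: int) -> np.ndarray:
    if radius <= 0:
        return np.ones((1, 1), dtype=bool)
    r = np.arange(-radius, radius + 1)
    return (r[:, None] ** 2 + r[None, :] ** 2) <= radius**2


def generate_synthetic_em(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Generate one synthetic EM section and its binary membrane mask.

    Returns
    -------
    image : float64 array in [0, 1], shape (height, width)
    mask : uint8 array, 1 on membrane pixels, 0 elsewhere, same shape

    All randomness flows from ``spec.seed`` through one generator stream, so
    the same spec yields bit-identical outputs.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height, spec.width)

    # cell seed points; uniform random, deduplicated to keep n_cells regions
    n_px = spec.height * spec.width
    flat = rng.choice(n_px, size=spec.n_cells, replace=False)
    seeds = np.stack(np.unravel_index(flat, shape), axis=1)

    cells = _voronoi_labels(shape, seeds)
    edges = _voronoi_edge_mask(cells)
    mask = ndi.binary_dilation(edges, structure=_disk(spec.membrane_width // 2))

    image = np.full(shape, spec.cytoplasm_mean, dtype=np.float64)

    if spec.texture_sd > 0:
        # per-cell texture: one smooth Gaussian field modulated per cell so
        # interiors differ in texture, as real cytoplasm does
        field = rng.normal(0.0, 1.0, shape)
        field = ndi.gaussian_filter(field, 2.0)
        sd = field.std()
        if sd > 0:
            field /= sd
        gains = rng.uniform(0.5, 1.5, spec.n_cells)
        image += spec.texture_sd * gains[cells] * field

    # organelles: dark ellipses strictly inside cells, the confusers that the
    # postprocessing stage exists to remove
    if spec.organelle_density > 0:
        interior = ~ndi.binary_dilation(mask, structure=_disk(2))
        rows, cols = np.indices(shape)
        for cell_id in range(spec.n_cells):
            if rng.random() >= spec.organelle_density:
                continue
            inside = (cells == cell_id) & interior
            idx = np.flatnonzero(inside)
            if idx.size < 25:
                continue
            center = np.unravel_index(rng.choice(idx), shape)
            a = rng.uniform(2.0, 6.0)
            b = rng.uniform(2.0, 6.0)
            theta = rng.uniform(0.0, np.pi)
            dy = rows - center[0]
            dx = cols - center[1]
            u = dy * np.cos(theta) + dx * np.sin(theta)
            v = -dy * np.sin(theta) + dx * np.cos(theta)
            blob = ((u / a) ** 2 + (v / b) ** 2 <= 1.0) & inside
            image[blob] = spec.organelle_mean

    image[mask] = spec.membrane_mean

    if spec.blur_sigma > 0:
        image = ndi.gaussian_filter(image, spec.blur_sigma, mode="reflect")
    if spec.noise_sd > 0:
        image += rng.normal(0.0, spec.noise_sd, shape)

    return np.clip(image, 0.0, 1.0), mask.astype(np.uint8)


def generate_stack(
    spec: SyntheticSpec, n_sections: int
) -> tuple[np.ndarray, np.ndarray]:
    """Generate ``n_sections`` independent sections as (images, masks) stacks.

    Section ``i`` uses seed ``spec.seed + i``; sections carry no 3-D
    consistency (the method under test is strictly per-2-D-section).
    """
    images, masks = [], []
    for i in range(n_sections):
        img, gt = generate_synthetic_em(replace(spec, seed=spec.seed + i))
        images.append(img)
        masks.append(gt)
    return np.stack(images), np.stack(masks)
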