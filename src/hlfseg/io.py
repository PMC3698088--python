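"""Reading and writing images, stacks and sample tables.

Images are 8- or 16-bit grayscale PNG or TIFF on disk and float arrays in
[0, 1] in memory; stacks are multipage TIFFs with one page per section.
Ground-truth membrane masks follow the challenge convention that membranes
are dark, so a label image is binarized as membrane = below half intensity
(a {0,1} mask with 1 = membrane passes through unchanged).
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile


def _to_float(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):  # RGB(A) -> luminance
        arr = arr[..., :3].mean(axis=-1)
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return arr.astype(np.float64) / info.max
    return np.clip(arr.astype(np.float64), 0.0, 1.0)


def read_image(path) -> np.ndarray:
    """Read a grayscale image (or stack) as float(s) in [0, 1]."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    return _to_float(arr)


def read_stack(path) -> list[np.ndarray]:
    """Read an image file as a list of 2-D sections."""
    arr = read_image(path)
    return [arr] if arr.ndim == 2 else [s for s in arr]


def read_label_image(path) -> np.ndarray:
    """Read a membrane label image as a {0,1} mask with 1 = membrane."""
    return binarize_labels(read_image(path))


def binarize_labels(arr: np.ndarray) -> np.ndarray:
    """Dark pixels (< 0.5) are membrane, unless already a {0,1} mask."""
    vals = np.unique(arr)
    if set(np.round(vals, 6)) <= {0.0, 1.0}:
        # ambiguous: a binary image; treat 1 as membrane only if membranes
        # are the minority class, else follow the dark-is-membrane rule
        ones = (arr == 1.0).mean()
        return (arr == 1.0).astype(np.uint8) if ones <= 0.5 else (arr == 0.0).astype(np.uint8)
    return (arr < 0.5).astype(np.uint8)


def write_image(path, img: np.ndarray) -> None:
    """Write a float image in [0, 1] (or a stack of them) as 8-bit grayscale."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.clip(np.asarray(img, dtype=np.float64), 0.0, 1.0)
    u8 = np.round(data * 255).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, u8)
    else:
        iio.imwrite(path, u8)


def write_probability_map(path, prob: np.ndarray) -> None:
    """Write a probability map as 32-bit float TIFF (or scaled 8-bit PNG)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, np.asarray(prob, dtype=np.float32))
    else:
        write_image(path, prob)


def write_label_map(path, labels: np.ndarray) -> None:
    """Write an integer label map as 16- or 32-bit TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    labels = np.asarray(labels)
    dtype = np.uint16 if labels.max() < 2**16 else np.uint32
    tifffile.imwrite(path, labels.astype(dtype))


def write_sample_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_sample_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
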