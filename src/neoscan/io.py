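"""Reading and writing 8-bit grayscale rasters (PNG/TIFF) and masks."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .preprocess import as_gray

__all__ = ["read_gray", "write_gray", "write_mask", "read_mask"]


def read_gray(path: str | Path) -> np.ndarray:
    """Read an 8-bit grayscale PNG/TIFF; collapses redundant channels."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        # accept RGB(A) exports of gray frames when all channels agree
        rgb = arr[..., :3]
        if not (rgb[..., 0] == rgb[..., 1]).all() or not (rgb[..., 1] == rgb[..., 2]).all():
            raise ValueError(f"{path}: not a grayscale image")
        arr = rgb[..., 0]
    return as_gray(arr)


def write_gray(path: str | Path, image: np.ndarray) -> None:
    iio.imwrite(Path(path), as_gray(image))


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a boolean mask as a 0/255 PNG."""
    m = np.asarray(mask, bool)
    iio.imwrite(Path(path), (m.astype(np.uint8)) * 255)


def read_mask(path: str | Path) -> np.ndarray:
    return read_gray(path) > 127
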