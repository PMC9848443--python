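"""Preprocessing for B-mode cranial ultrasound frames.

Three stages, applied in order before any quantification:

1. :func:`crop_black_margins` — remove the black annotation margins that
   surround the exported sector image, by thresholding the per-row /
   per-column count of zero-valued pixels.
2. :func:`adaptive_median_filter` — suppress isolated impulse noise while
   preserving the boundary of hyperechoic regions, using the two-level
   (window-growing) adaptive median scheme.
3. :func:`clahe` — contrast-limited adaptive histogram equalization:
   per-tile equalization with histogram clipping and inter-tile bilinear
   blending.  Plain :func:`histogram_equalize` is kept as the comparison
   baseline (it over-enhances bright regions on frames that mix bright
   and dark areas).

All stages take and return 2D uint8 rasters with ``L = 256`` gray levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "CropBounds",
    "AmfConfig",
    "ClaheConfig",
    "crop_black_margins",
    "adaptive_median_filter",
    "histogram_equalize",
    "equalization_map",
    "clip_histogram",
    "clahe",
]

GRAY_LEVELS = 256


def as_gray(image: np.ndarray) -> np.ndarray:
    """Validate and return a 2D uint8 gray raster."""
    img = np.asarray(image)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a nonempty 2D gray image")
    if img.dtype != np.uint8:
        if np.issubdtype(img.dtype, np.integer) and img.min() >= 0 and img.max() <= 255:
            img = img.astype(np.uint8)
        else:
            raise ValueError("gray image must be 8-bit (values in [0, 255])")
    return img


def round_half_away(x: np.ndarray | float) -> np.ndarray | float:
    """Round half away from zero (all pipeline values are non-negative)."""
    return np.floor(np.asarray(x, dtype=float) + 0.5)


@dataclass(frozen=True)
class CropBounds:
    """Half-open [start, end) crop window in pixel indices."""

    row_start: int
    row_end: int
    col_start: int
    col_end: int

    def __post_init__(self) -> None:
        if not (0 <= self.row_start < self.row_end):
            raise ValueError("invalid row bounds")
        if not (0 <= self.col_start < self.col_end):
            raise ValueError("invalid column bounds")

    def apply(self, image: np.ndarray) -> np.ndarray:
        return image[self.row_start:self.row_end, self.col_start:self.col_end]

    def as_dict(self) -> dict[str, int]:
        return {"row_start": self.row_start, "row_end": self.row_end,
                "col_start": self.col_start, "col_end": self.col_end}


@dataclass(frozen=True)
class AmfConfig:
    """Adaptive-median-filter window limits (both odd, initial <= max)."""

    initial_window: int = 3
    max_window: int = 7

    def __post_init__(self) -> None:
        if self.initial_window < 3 or self.initial_window % 2 == 0:
            raise ValueError("initial_window must be an odd integer >= 3")
        if self.max_window < self.initial_window or self.max_window % 2 == 0:
            raise ValueError("max_window must be odd and >= initial_window")


@dataclass(frozen=True)
class ClaheConfig:
    """CLAHE grid and clip configuration.

    ``tile_rows``/``tile_cols`` give the tile *grid* (default 8x8 tiles);
    each tile of m x n pixels is equalized on its own clipped histogram.
    The truncation value is ``C = clip_factor * G_bar`` where ``G_bar`` is
    the tile's average pixel count per occupied gray level; a clip_factor
    of ``inf`` degenerates to unclipped per-tile equalization.
    """

    tile_rows: int = 8
    tile_cols: int = 8
    clip_factor: float = 4.0

    def __post_init__(self) -> None:
        if self.tile_rows < 1 or self.tile_cols < 1:
            raise ValueError("tile grid must be at least 1x1")
        if self.clip_factor < 1:
            raise ValueError("clip_factor must be >= 1")


def crop_black_margins(image: np.ndarray, zero_fraction_threshold: float = 0.95,
                       ) -> tuple[CropBounds, np.ndarray]:
    """Crop the black annotation margins from an exported ultrasound frame.

    A row (column) is a margin row (column) iff its fraction of zero-valued
    pixels is >= ``zero_fraction_threshold``; the crop bounds are the first
    and last non-margin row and column scanned inward from each edge.

    Returns
    -------
    (CropBounds, numpy.ndarray)
        The bounds and the image restricted to them.

    Raises
    ------
    ValueError
        Threshold outside (0, 1], or no content region (fully black image).
    """
    img = as_gray(image)
    if not 0 < zero_fraction_threshold <= 1:
        raise ValueError("zero_fraction_threshold must be in (0, 1]")
    zero = img == 0
    row_margin = zero.mean(axis=1) >= zero_fraction_threshold
    col_margin = zero.mean(axis=0) >= zero_fraction_threshold
    if row_margin.all() or col_margin.all():
        raise ValueError("no content region: image is entirely margin")
    keep_rows = np.flatnonzero(~row_margin)
    keep_cols = np.flatnonzero(~col_margin)
    bounds = CropBounds(int(keep_rows[0]), int(keep_rows[-1]) + 1,
                        int(keep_cols[0]), int(keep_cols[-1]) + 1)
    return bounds, bounds.apply(img)


def adaptive_median_filter(image: np.ndarray, config: AmfConfig = AmfConfig(),
                           ) -> np.ndarray:
    """Two-level adaptive median filter.

    For each pixel with value f, starting at the initial window size:

    * Level A — compute z_min, z_med, z_max over the window.  If
      ``z_min < z_med < z_max`` the window median is not an impulse: go to
      Level B.  Otherwise grow the window by 2 and repeat while the window
      does not exceed the maximum size; if it would, output z_med (from
      the largest window).
    * Level B — if ``z_min < f < z_max`` the pixel itself is not an
      impulse: output f unchanged.  Otherwise output z_med.

    Borders are handled by edge replication.  Output values always lie
    within the input's [min, max] range.
    """
    img = as_gray(image)
    out = np.empty_like(img)
    undecided = np.ones(img.shape, dtype=bool)
    z_med = img
    for window in range(config.initial_window, config.max_window + 1, 2):
        z_min = ndimage.minimum_filter(img, size=window, mode="nearest")
        z_max = ndimage.maximum_filter(img, size=window, mode="nearest")
        z_med = ndimage.median_filter(img, size=window, mode="nearest")
        level_a = (z_min < z_med) & (z_med < z_max) & undecided
        if level_a.any():
            level_b = np.where((z_min < img) & (img < z_max), img, z_med)
            out[level_a] = level_b[level_a]
            undecided &= ~level_a
        if not undecided.any():
            break
    out[undecided] = z_med[undecided]
    return out


def equalization_map(histogram: np.ndarray, levels: int = GRAY_LEVELS) -> np.ndarray:
    """Gray-level mapping of histogram equalization.

    Maps level k to ``round((L-1) * cum_fraction(k))`` where cum_fraction
    is the cumulative histogram fraction; monotone non-decreasing by
    construction.  Rounding is half away from zero.
    """
    hist = np.asarray(histogram, dtype=np.int64)
    total = hist.sum()
    if total <= 0:
        raise ValueError("empty histogram")
    cum = np.cumsum(hist) / total
    return round_half_away((levels - 1) * cum).astype(np.uint8)


def histogram_equalize(image: np.ndarray) -> np.ndarray:
    """Global histogram equalization of an 8-bit gray image."""
    img = as_gray(image)
    hist = np.bincount(img.ravel(), minlength=GRAY_LEVELS)
    return equalization_map(hist)[img]


def clip_histogram(histogram: np.ndarray, clip_factor: float) -> np.ndarray:
    """Clip a tile histogram at C = clip_factor * G_bar and redistribute.

    G_bar is the average pixel count over the tile's occupied gray levels.
    Counts above the (integer-rounded) truncation value C are capped; the
    total excess S is redistributed evenly over the occupied levels,
    S // G_n to each and the integer residual one unit each to the
    lowest-indexed occupied levels.  The histogram sum is conserved
    exactly.  A single pass is made: redistribution may lift a bin above C
    again, which is accepted.
    """
    hist = np.asarray(histogram, dtype=np.int64).copy()
    occupied = hist > 0
    g_n = int(occupied.sum())
    if g_n == 0:
        raise ValueError("empty histogram")
    if not np.isfinite(clip_factor):
        return hist
    g_bar = hist.sum() / g_n
    c = max(int(round_half_away(clip_factor * g_bar)), 1)
    excess = int(np.maximum(hist - c, 0).sum())
    if excess == 0:
        return hist
    hist = np.minimum(hist, c)
    base, residual = divmod(excess, g_n)
    hist[occupied] += base
    if residual:
        hist[np.flatnonzero(occupied)[:residual]] += 1
    return hist


def _tile_edges(n_pixels: int, n_tiles: int) -> np.ndarray:
    base = n_pixels // n_tiles
    if base < 1:
        raise ValueError("tile grid finer than the image (tile larger than image)")
    edges = np.arange(n_tiles + 1) * base
    edges[-1] = n_pixels  # ragged last tile absorbs the remainder
    return edges


def clahe(image: np.ndarray, config: ClaheConfig = ClaheConfig()) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    The image is partitioned into a ``tile_rows x tile_cols`` grid.  Each
    tile's histogram is clipped and redistributed (:func:`clip_histogram`)
    and equalized on its own pixel count (:func:`equalization_map`).
    Every pixel is then remapped by bilinear interpolation between the
    mappings of the four nearest tile centers; outside the outer
    tile-center lattice the nearest mapping is used (clamped), so a 1x1
    grid with a large clip factor reproduces plain histogram equalization
    bit-exactly.
    """
    img = as_gray(image)
    h, w = img.shape
    row_edges = _tile_edges(h, config.tile_rows)
    col_edges = _tile_edges(w, config.tile_cols)
    n_tr, n_tc = config.tile_rows, config.tile_cols

    maps = np.empty((n_tr, n_tc, GRAY_LEVELS), dtype=np.uint8)
    for i in range(n_tr):
        for j in range(n_tc):
            tile = img[row_edges[i]:row_edges[i + 1], col_edges[j]:col_edges[j + 1]]
            hist = np.bincount(tile.ravel(), minlength=GRAY_LEVELS)
            maps[i, j] = equalization_map(clip_histogram(hist, config.clip_factor))

    centers_r = (row_edges[:-1] + row_edges[1:] - 1) / 2.0
    centers_c = (col_edges[:-1] + col_edges[1:] - 1) / 2.0
    fi = np.interp(np.arange(h), centers_r, np.arange(n_tr, dtype=float))
    fj = np.interp(np.arange(w), centers_c, np.arange(n_tc, dtype=float))
    i0 = np.minimum(fi.astype(int), n_tr - 1)
    j0 = np.minimum(fj.astype(int), n_tc - 1)
    i1 = np.minimum(i0 + 1, n_tr - 1)
    j1 = np.minimum(j0 + 1, n_tc - 1)
    tr = (fi - i0)[:, None]
    tc = (fj - j0)[None, :]

    i0g, i1g = i0[:, None], i1[:, None]
    j0g, j1g = j0[None, :], j1[None, :]
    m00 = maps[i0g, j0g, img].astype(float)
    m01 = maps[i0g, j1g, img].astype(float)
    m10 = maps[i1g, j0g, img].astype(float)
    m11 = maps[i1g, j1g, img].astype(float)
    blended = ((1 - tr) * ((1 - tc) * m00 + tc * m01)
               + tr * ((1 - tc) * m10 + tc * m11))
    return np.clip(round_half_away(blended), 0, GRAY_LEVELS - 1).astype(np.uint8)
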