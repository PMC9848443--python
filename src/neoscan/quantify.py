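"""Echo-intensity and echo-homogeneity quantification.

Two read-outs are computed over regions of a preprocessed frame:

* **Echo intensity** — the gray mean M = sum_r r * p(r) of a region and
  the *relative gray value*, the ROI mean divided by the mean of a
  circular reference region, on a percent scale (x100).  Hyperechoic
  white matter shows a raised relative gray value.
* **Echo homogeneity** — gray-level co-occurrence matrix (GLCM) texture
  features per compass direction: energy (ENE, angular second moment),
  inverse difference moment (IDM), contrast (CON, inertia) and entropy
  (ENT), plus the aggregate columns E-W, N-S, Cross (mean of the four
  axis-aligned directions) and Circle (mean of all eight).  Heterogeneous
  tissue shows high ENT/CON and low ENE/IDM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import GRAY_LEVELS, as_gray
from .roi import RegionMask

__all__ = [
    "GlcmConfig",
    "GlcmMatrix",
    "DirectionalAggregates",
    "TextureFeatureTable",
    "EchoIntensityReport",
    "DIRECTIONS",
    "OFFSETS",
    "AGGREGATE_COLUMNS",
    "gray_mean",
    "relative_gray_value",
    "quantize",
    "glcm",
    "glcm_features",
    "aggregate_directions",
    "homogeneity_report",
    "intensity_report",
]

#: Compass directions in table column order, with (row, col) offsets.
#: Row indices grow downward, so "north" is a negative row offset.
OFFSETS: dict[str, tuple[int, int]] = {
    "E": (0, 1), "N-E": (-1, 1), "N": (-1, 0), "N-W": (-1, -1),
    "W": (0, -1), "S-W": (1, -1), "S": (1, 0), "S-E": (1, 1),
}
DIRECTIONS: tuple[str, ...] = tuple(OFFSETS)
AGGREGATE_COLUMNS: tuple[str, ...] = ("E-W", "N-S", "Cross", "Circle")
FEATURES: tuple[str, ...] = ("ENE", "IDM", "CON", "ENT")


@dataclass(frozen=True)
class GlcmConfig:
    """GLCM computation parameters.

    levels : quantization bins G (gray values are binned by
        ``floor(value * G / 256)`` before pairing); distance : pixel
        offset multiplier d; entropy_log_base : 2 (bits) or e (nats);
        symmetric : count each ordered pair in both directions (adds the
        transpose), which makes all four features equal for opposite
        directions.
    """

    levels: int = 16
    distance: int = 1
    entropy_log_base: float = 2.0
    symmetric: bool = True

    def __post_init__(self) -> None:
        if not 2 <= self.levels <= 256:
            raise ValueError("levels must be in [2, 256]")
        if self.distance < 1:
            raise ValueError("distance must be >= 1")
        if self.entropy_log_base not in (2.0, 2, math.e):
            raise ValueError("entropy_log_base must be 2 or e")


@dataclass(frozen=True)
class GlcmMatrix:
    """Normalized co-occurrence matrix for one direction/distance."""

    P: np.ndarray
    direction: str
    distance: int

    def __post_init__(self) -> None:
        p = np.asarray(self.P, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("P must be square")
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("P must be a probability matrix (sum 1)")
        object.__setattr__(self, "P", p)


@dataclass(frozen=True)
class DirectionalAggregates:
    ew: float
    ns: float
    cross: float
    circle: float


def gray_mean(image: np.ndarray, mask: RegionMask | np.ndarray) -> float:
    """Average gray level M = sum_r r*p(r) over the masked pixels.

    Identically the arithmetic mean of the masked pixel values; kept at
    full floating precision.
    """
    img = as_gray(image)
    m = mask.mask if isinstance(mask, RegionMask) else np.asarray(mask, bool)
    if m.shape != img.shape:
        raise ValueError("mask dimensions must match the image")
    if not m.any():
        raise ValueError("empty mask")
    values = img[m]
    p = np.bincount(values, minlength=GRAY_LEVELS) / values.size
    return float(np.arange(GRAY_LEVELS) @ p)


def relative_gray_value(roi_mean: float, reference_mean: float) -> float:
    """Relative gray value: 100 * roi_mean / reference_mean.

    The percent scale follows the reported convention for normalized echo
    intensity (a ratio of 0.570813 is reported as 57.0813).
    """
    if reference_mean <= 0:
        raise ValueError("reference mean must be positive")
    return 100.0 * roi_mean / reference_mean


def quantize(image: np.ndarray, levels: int) -> np.ndarray:
    """Bin gray values into ``levels`` equal-width bins.

    level = floor(value * G / 256), clamped to G-1; monotone in the pixel
    value and the identity for G = 256.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    img = as_gray(image)
    q = (img.astype(np.int64) * levels) // GRAY_LEVELS
    return np.minimum(q, levels - 1).astype(np.uint8)


def glcm(image: np.ndarray, mask: RegionMask | np.ndarray, direction: str,
         config: GlcmConfig = GlcmConfig()) -> GlcmMatrix:
    """Gray-level co-occurrence matrix over a masked region.

    Counts ordered pairs (q[p], q[p + d*offset]) over all pixels p where
    both endpoints lie inside the mask, with q the quantized image.  If
    symmetric, the transpose is added before normalization to sum 1.
    """
    if direction not in OFFSETS:
        raise ValueError(f"unknown direction {direction!r}")
    img = as_gray(image)
    m = mask.mask if isinstance(mask, RegionMask) else np.asarray(mask, bool)
    if m.shape != img.shape:
        raise ValueError("mask dimensions must match the image")
    q = quantize(img, config.levels)
    dr, dc = OFFSETS[direction]
    dr *= config.distance
    dc *= config.distance
    h, w = img.shape
    src_r = slice(max(0, -dr), h - max(0, dr))
    src_c = slice(max(0, -dc), w - max(0, dc))
    dst_r = slice(max(0, dr), h - max(0, -dr))
    dst_c = slice(max(0, dc), w - max(0, -dc))
    valid = m[src_r, src_c] & m[dst_r, dst_c]
    if not valid.any():
        raise ValueError(f"no valid pixel pair for direction {direction}")
    a = q[src_r, src_c][valid].astype(np.int64)
    b = q[dst_r, dst_c][valid].astype(np.int64)
    counts = np.zeros((config.levels, config.levels), dtype=np.int64)
    np.add.at(counts, (a, b), 1)
    if config.symmetric:
        counts = counts + counts.T
    return GlcmMatrix(counts / counts.sum(), direction, config.distance)


def glcm_features(matrix: GlcmMatrix | np.ndarray,
                  entropy_log_base: float = 2.0) -> dict[str, float]:
    """ENE, IDM, CON, ENT of a normalized co-occurrence matrix.

    ENE = sum P^2 (energy / angular second moment); IDM = sum
    P/(1+(i-j)^2); CON = sum (i-j)^2 P (inertia); ENT = -sum_{P>0}
    P log P in the configured base.
    """
    p = matrix.P if isinstance(matrix, GlcmMatrix) else np.asarray(matrix, float)
    i, j = np.indices(p.shape)
    d2 = (i - j) ** 2
    nz = p[p > 0]
    return {
        "ENE": float(np.sum(p * p)),
        "IDM": float(np.sum(p / (1.0 + d2))),
        "CON": float(np.sum(d2 * p)),
        "ENT": float(-(nz * np.log(nz)).sum() / math.log(entropy_log_base)),
    }


def aggregate_directions(per_direction: Mapping[str, float]) -> DirectionalAggregates:
    """Aggregate the 8 directional values into E-W, N-S, Cross, Circle.

    E-W = mean(E, W); N-S = mean(N, S); Cross = mean(E, N, W, S);
    Circle = mean of all eight compass directions.
    """
    missing = [d for d in DIRECTIONS if d not in per_direction]
    if missing:
        raise ValueError(f"missing directions: {missing}")
    v = {d: float(per_direction[d]) for d in DIRECTIONS}
    return DirectionalAggregates(
        ew=(v["E"] + v["W"]) / 2.0,
        ns=(v["N"] + v["S"]) / 2.0,
        cross=(v["E"] + v["N"] + v["W"] + v["S"]) / 4.0,
        circle=sum(v.values()) / 8.0,
    )


@dataclass(frozen=True)
class TextureFeatureTable:
    """Directional GLCM features of one region: rows ENE/IDM/CON/ENT,
    columns the 8 compass directions plus E-W, N-S, Cross, Circle."""

    per_direction: dict[str, dict[str, float]]
    config: GlcmConfig = field(default_factory=GlcmConfig)

    def to_frame(self) -> pd.DataFrame:
        rows = {}
        for feat in FEATURES:
            vals = self.per_direction[feat]
            agg = aggregate_directions(vals)
            rows[feat] = [vals[d] for d in DIRECTIONS] + [agg.ew, agg.ns,
                                                          agg.cross, agg.circle]
        return pd.DataFrame.from_dict(
            rows, orient="index", columns=list(DIRECTIONS) + list(AGGREGATE_COLUMNS))


@dataclass(frozen=True)
class EchoIntensityReport:
    """ROI gray means, reference mean and relative gray values (percent)."""

    roi_means: tuple[float, ...]
    reference_mean: float
    relative_values: tuple[float, ...]

    def to_frame(self) -> pd.DataFrame:
        labels = [f"Average pixel gray value of ROI {i + 1}"
                  for i in range(len(self.roi_means))]
        labels.append("Average pixel gray value of reference area")
        labels += [f"Relative gray value of ROI {i + 1}"
                   for i in range(len(self.relative_values))]
        values = list(self.roi_means) + [self.reference_mean] + list(self.relative_values)
        return pd.DataFrame({"value": values}, index=labels)


def homogeneity_report(image: np.ndarray, masks: Sequence[RegionMask | np.ndarray],
                       config: GlcmConfig = GlcmConfig(),
                       ) -> list[TextureFeatureTable]:
    """Per-ROI directional texture tables (one table per mask)."""
    tables = []
    for mask in masks:
        per_feature: dict[str, dict[str, float]] = {f: {} for f in FEATURES}
        for direction in DIRECTIONS:
            feats = glcm_features(glcm(image, mask, direction, config),
                                  config.entropy_log_base)
            for f in FEATURES:
                per_feature[f][direction] = feats[f]
        tables.append(TextureFeatureTable(per_feature, config))
    return tables


def intensity_report(image: np.ndarray, roi_masks: Sequence[RegionMask | np.ndarray],
                     reference_mask: RegionMask | np.ndarray) -> EchoIntensityReport:
    """Gray means and relative gray values of ROIs against a reference."""
    roi_means = tuple(gray_mean(image, m) for m in roi_masks)
    ref_mean = gray_mean(image, reference_mask)
    relatives = tuple(relative_gray_value(m, ref_mean) for m in roi_means)
    return EchoIntensityReport(roi_means, ref_mean, relatives)
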