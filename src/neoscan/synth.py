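"""Synthetic cranial-ultrasound phantoms with known ground truth.

No patient images ship with this package, so every pipeline stage is
exercised on phantoms that emulate the relevant structure of a B-mode
cranial frame:

* speckle-textured parenchyma (multiplicative gamma noise, unit mean,
  standard deviation set by ``speckle_scale`` — the conventional
  multi-look speckle model);
* hyperechoic lesions: polygonal regions with a raised mean gray level
  and an optional low-frequency heterogeneity modulation that raises
  GLCM contrast/entropy the way heterogeneous white matter does;
* a surrounding black margin band (gray 0), the target of the crop stage;
* optional salt-and-pepper impulse noise, the target of the adaptive
  median filter.

Identical specs (including the seed) produce bit-identical phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .preprocess import round_half_away
from .roi import RegionMask, polygon_mask

__all__ = ["LesionSpec", "PhantomSpec", "generate_phantom", "add_impulse_noise"]

_HET_GRID_SPACING = 8  # coarse-grid pitch (px) of the heterogeneity field


@dataclass(frozen=True)
class LesionSpec:
    """One polygonal lesion: vertices in (row, col), mean gray level in
    [0, 255], and a heterogeneity scale >= 0 (relative amplitude of the
    low-frequency mean modulation inside the lesion)."""

    vertices: tuple[tuple[float, float], ...]
    mean: float
    heterogeneity: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "vertices",
                           tuple((float(r), float(c)) for r, c in self.vertices))
        if len(self.vertices) < 3:
            raise ValueError("lesion polygon needs at least 3 vertices")
        if not 0 <= self.mean <= 255:
            raise ValueError("lesion mean gray level must be in [0, 255]")
        if self.heterogeneity < 0:
            raise ValueError("heterogeneity scale must be >= 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic cranial-ultrasound phantom."""

    height: int = 256
    width: int = 256
    background_mean: float = 100.0
    speckle_scale: float = 0.1
    lesions: tuple[LesionSpec, ...] = ()
    margin_width: int = 0
    impulse_noise_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("phantom dimensions must be positive")
        if not 0 <= self.background_mean <= 255:
            raise ValueError("background mean must be in [0, 255]")
        if self.speckle_scale < 0:
            raise ValueError("speckle_scale must be >= 0")
        if not 0 <= self.margin_width < min(self.height, self.width) / 2:
            raise ValueError("margin_width must be < min(height, width)/2")
        if not 0 <= self.impulse_noise_fraction <= 1:
            raise ValueError("impulse_noise_fraction must be in [0, 1]")
        object.__setattr__(self, "lesions", tuple(
            lesion if isinstance(lesion, LesionSpec) else LesionSpec(*lesion)
            for lesion in self.lesions))

    def as_dict(self) -> dict:
        return {
            "height": self.height, "width": self.width,
            "background_mean": self.background_mean,
            "speckle_scale": self.speckle_scale,
            "lesions": [{"vertices": [list(v) for v in l.vertices],
                         "mean": l.mean, "heterogeneity": l.heterogeneity}
                        for l in self.lesions],
            "margin_width": self.margin_width,
            "impulse_noise_fraction": self.impulse_noise_fraction,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PhantomSpec":
        data = dict(data)
        lesions = tuple(
            LesionSpec(tuple(tuple(v) for v in l["vertices"]), l["mean"],
                       l.get("heterogeneity", 0.0))
            for l in data.pop("lesions", []))
        return cls(lesions=lesions, **data)


def _smooth_field(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Zero-mean low-frequency field: coarse standard-normal grid,
    bilinearly upsampled to the full raster."""
    h, w = shape
    gh = max(h // _HET_GRID_SPACING, 2)
    gw = max(w // _HET_GRID_SPACING, 2)
    coarse = rng.standard_normal((gh, gw))
    zoom = (h / gh, w / gw)
    return ndimage.zoom(coarse, zoom, order=1, mode="nearest", grid_mode=True)


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, list[RegionMask]]:
    """Render a phantom and return it with its ground-truth lesion masks.

    The mean-gray field is the background mean everywhere, overwritten by
    each lesion's (possibly modulated) mean inside its polygon; lesion
    modulation has zero expectation, so lesion pixels have expected value
    equal to the lesion mean before noise.  Speckle multiplies the mean
    field by a unit-mean gamma factor; values are clipped to [0, 255] and
    rounded half away from zero.  Impulse noise, if any, is confined to
    the interior so the margin band stays exactly 0.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    mean_field = np.full((h, w), float(spec.background_mean))

    masks: list[RegionMask] = []
    interior = np.zeros((h, w), dtype=bool)
    mw = spec.margin_width
    interior[mw:h - mw if mw else h, mw:w - mw if mw else w] = True

    for lesion in spec.lesions:
        region = polygon_mask(lesion.vertices, h, w)
        # Always drawn so phantoms differing only in heterogeneity share
        # the same downstream speckle realization at equal seeds.
        field_ = _smooth_field((h, w), rng)
        modulation = np.maximum(lesion.heterogeneity * field_, -0.95)
        lesion_field = lesion.mean * (1.0 + modulation)
        mean_field[region.mask] = lesion_field[region.mask]
        visible = region.mask & interior
        masks.append(RegionMask(visible, kind="roi",
                                geometry=dict(region.geometry)))

    if spec.speckle_scale > 0:
        shape = 1.0 / spec.speckle_scale**2
        factor = rng.gamma(shape, 1.0 / shape, size=(h, w))
        pixels = mean_field * factor
    else:
        pixels = mean_field

    image = round_half_away(np.clip(pixels, 0, 255)).astype(np.uint8)

    if spec.impulse_noise_fraction > 0:
        block = image[mw:h - mw if mw else h, mw:w - mw if mw else w]
        noisy = add_impulse_noise(block, spec.impulse_noise_fraction,
                                  rng.integers(0, 2**31 - 1))
        image[mw:h - mw if mw else h, mw:w - mw if mw else w] = noisy

    image[~interior] = 0
    return image, masks


def add_impulse_noise(image: np.ndarray, fraction: float,
                      seed: int) -> np.ndarray:
    """Replace exactly round(fraction * pixel_count) pixels with salt or
    pepper values.

    Half of the replaced pixels (rounding up) are set to 0 and the rest
    to 255; the replaced coordinates are reproducible from the seed.  The
    input is not modified.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    img = np.asarray(image)
    out = img.copy()
    n_total = img.size
    n_replace = int(round_half_away(fraction * n_total))
    if n_replace == 0:
        return out
    rng = np.random.default_rng(seed)
    flat = rng.choice(n_total, size=n_replace, replace=False)
    n_pepper = (n_replace + 1) // 2
    out.flat[flat[:n_pepper]] = 0
    out.flat[flat[n_pepper:]] = 255
    return out
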