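"""Region-of-interest geometry.

The echogenicity workflow needs two kinds of regions on a preprocessed
B-mode frame: a freehand-style region of interest (here a polygon given by
its vertices) and a fixed-size circular reference region used to normalise
echo intensity.  Both are rasterised to boolean masks with a deterministic
pixel-center convention: pixel ``(i, j)`` has its center at coordinates
``(i, j)`` in (row, col) units, 0-based.

Rasterisation rules
-------------------
* Polygon: a pixel is selected iff its center lies inside the closed
  polygon under the even-odd rule; centers exactly on an edge are selected
  (the region is closed).
* Circle: a pixel is selected iff the Euclidean distance from its center
  to the circle center is ``<= radius``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

__all__ = ["RegionMask", "polygon_mask", "circle_mask", "mask_boundary"]

_EDGE_TOL = 1e-9


@dataclass(frozen=True)
class RegionMask:
    """Boolean raster selecting region pixels, with provenance geometry.

    Attributes
    ----------
    mask : numpy.ndarray of bool
        Raster with the target image's dimensions; True marks selected pixels.
    kind : str
        Either ``"roi"`` or ``"reference"``.
    geometry : dict
        Source geometry: ``{"vertices": [...]}`` for polygons or
        ``{"center": (r, c), "radius": r}`` for circles.
    """

    mask: np.ndarray
    kind: str = "roi"
    geometry: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError("mask must be a 2D raster")
        if not m.any():
            raise ValueError("mask selects no pixels")
        object.__setattr__(self, "mask", m)

    @property
    def size(self) -> int:
        return int(self.mask.sum())


def _on_segment(pr: np.ndarray, pc: np.ndarray, a: tuple[float, float],
                b: tuple[float, float]) -> np.ndarray:
    """Vectorised test: does point (pr, pc) lie on segment a-b?"""
    ar, ac = a
    br, bc = b
    cross = (br - ar) * (pc - ac) - (bc - ac) * (pr - ar)
    on_line = np.abs(cross) <= _EDGE_TOL * (1.0 + abs(br - ar) + abs(bc - ac))
    dot = (pr - ar) * (br - ar) + (pc - ac) * (bc - ac)
    seg_len2 = (br - ar) ** 2 + (bc - ac) ** 2
    if seg_len2 == 0.0:  # degenerate edge (repeated vertex)
        return on_line & (np.abs(pr - ar) <= _EDGE_TOL) & (np.abs(pc - ac) <= _EDGE_TOL)
    return on_line & (dot >= -_EDGE_TOL) & (dot <= seg_len2 + _EDGE_TOL)


def polygon_mask(vertices: Sequence[tuple[float, float]], image_height: int,
                 image_width: int) -> RegionMask:
    """Rasterise a closed polygon to a boolean mask.

    Parameters
    ----------
    vertices : sequence of (row, col)
        At least three vertices, all within the image bounds.  The polygon
        is closed implicitly (last vertex connects back to the first).
    image_height, image_width : int
        Dimensions of the target raster.

    Returns
    -------
    RegionMask
        Even-odd interior plus edge-touching pixel centers.

    Raises
    ------
    ValueError
        Fewer than 3 vertices, a vertex outside the image, or a polygon
        with empty interior (e.g. fully degenerate/self-cancelling).
    """
    verts = [(float(r), float(c)) for r, c in vertices]
    if len(verts) < 3:
        raise ValueError("polygon needs at least 3 vertices")
    for r, c in verts:
        if not (0 <= r <= image_height - 1 and 0 <= c <= image_width - 1):
            raise ValueError(f"vertex ({r}, {c}) outside image bounds")

    pr, pc = np.meshgrid(np.arange(image_height, dtype=float),
                         np.arange(image_width, dtype=float), indexing="ij")
    inside = np.zeros((image_height, image_width), dtype=bool)
    on_edge = np.zeros_like(inside)

    n = len(verts)
    for k in range(n):
        ar, ac = verts[k]
        br, bc = verts[(k + 1) % n]
        on_edge |= _on_segment(pr, pc, (ar, ac), (br, bc))
        # Even-odd ray casting: horizontal ray in +col direction, the edge
        # crossing rule is half-open in row to count each crossing once.
        crosses = (ar > pr) != (br > pr)
        if np.any(crosses):
            with np.errstate(divide="ignore", invalid="ignore"):
                col_at = ac + (pr - ar) * (bc - ac) / (br - ar)
            inside ^= crosses & (pc < col_at)

    selected = inside | on_edge
    if not selected.any():
        raise ValueError("polygon has empty interior")
    return RegionMask(selected, kind="roi", geometry={"vertices": verts})


def circle_mask(center: tuple[float, float], radius: float, image_height: int,
                image_width: int) -> RegionMask:
    """Rasterise a disc: pixel centers within ``radius`` of ``center``."""
    cr, cc = float(center[0]), float(center[1])
    if radius <= 0:
        raise ValueError("radius must be positive")
    if not (0 <= cr <= image_height - 1 and 0 <= cc <= image_width - 1):
        raise ValueError("circle center outside image")
    rr = np.arange(image_height, dtype=float)[:, None] - cr
    cc_ = np.arange(image_width, dtype=float)[None, :] - cc
    selected = rr * rr + cc_ * cc_ <= radius * radius
    if not selected.any():
        raise ValueError("circle selects no pixels")
    return RegionMask(selected, kind="reference",
                      geometry={"center": (cr, cc), "radius": float(radius)})


def mask_boundary(region: RegionMask | np.ndarray) -> list[tuple[int, int]]:
    """Boundary pixels of a mask.

    A selected pixel is a boundary pixel iff at least one of its
    4-neighbors is outside the mask or it sits on the image border.
    """
    mask = region.mask if isinstance(region, RegionMask) else np.asarray(region, bool)
    if not mask.any():
        raise ValueError("empty mask has no boundary")
    padded = np.pad(mask, 1, constant_values=False)
    interior = (padded[:-2, 1:-1] & padded[2:, 1:-1]
                & padded[1:-1, :-2] & padded[1:-1, 2:])
    boundary = mask & ~interior
    return [(int(r), int(c)) for r, c in np.argwhere(boundary)]
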