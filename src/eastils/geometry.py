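"""Raster/vector geometry helpers.

Conventions: coordinates are in µm with the origin at the tile's top-left
corner, x along columns, y along rows (y grows downward).  Pixel (i, j)
covers the half-open square [j*s, (j+1)*s) x [i*s, (i+1)*s) for pixel size
s, so a polygon built from pixel boxes has area exactly
``pixel_count * s**2`` — area accounting is unit-exact by construction.
"""

from __future__ import annotations

import numpy as np
import shapely
from shapely.geometry import Polygon
from shapely.geometry.base import BaseGeometry

__all__ = ["mask_to_polygon", "polygon_to_mask", "rasterized_area_um2"]


def mask_to_polygon(
    mask: np.ndarray,
    microns_per_pixel: float,
    origin_um: tuple[float, float] = (0.0, 0.0),
) -> BaseGeometry:
    """Union of pixel squares of a boolean mask, in µm coordinates.

    The returned polygon's area equals ``mask.sum() * microns_per_pixel**2``
    exactly (up to float rounding).
    """
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        return Polygon()
    s = float(microns_per_pixel)
    ox, oy = origin_um
    x0 = ox + cols * s
    y0 = oy + rows * s
    boxes = shapely.box(x0, y0, x0 + s, y0 + s)
    return shapely.union_all(boxes, grid_size=0)


def polygon_to_mask(
    poly: BaseGeometry,
    shape: tuple[int, int],
    microns_per_pixel: float,
    origin_um: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Rasterize a polygon: a pixel is inside iff its center is covered."""
    h, w = shape
    s = float(microns_per_pixel)
    ox, oy = origin_um
    jj, ii = np.meshgrid(np.arange(w), np.arange(h))
    xs = ox + (jj.ravel() + 0.5) * s
    ys = oy + (ii.ravel() + 0.5) * s
    pts = shapely.points(xs, ys)
    inside = shapely.covers(poly, pts)
    return inside.reshape(h, w)


def rasterized_area_um2(mask: np.ndarray, microns_per_pixel: float) -> float:
    """Area of a boolean mask in µm²."""
    return float(np.count_nonzero(mask)) * float(microns_per_pixel) ** 2
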