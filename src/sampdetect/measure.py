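"""Morphometry of particle masks and contours.

All particle sizing in the pipeline goes through this module: feret
(caliper) diameters, area, perimeter, circularity ``4*pi*A/P**2``, aspect
ratio ``feret_max/feret_min``, micrometre conversion and the four-way size
categorisation (small / medium / large / extra-large).

Conventions
-----------
* Coordinates are ``(x, y)`` with x to the right and y down, 0-based.
* A mask's boundary is traced with sub-pixel marching squares at level 0.5
  on the padded mask, so a ``w x h``-pixel rectangle measures ``w`` wide,
  not ``w - 1``: the traced polygon runs half a pixel outside the outermost
  pixel centres.  A single pixel therefore has ``feret_max == 1.0`` and at
  the default scale of 18 um/px reports 18 um — the system's lower limit of
  detection.
* Perimeter is the length of that traced polygon (not a pixel-edge count),
  which keeps circularity close to its continuum value; residual
  discretisation slack means circularity can slightly exceed 1 for small
  near-circular masks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage import measure as _skmeasure

__all__ = [
    "ShapeStats",
    "SIZE_CATEGORIES",
    "SIZE_BOUNDS_PX",
    "DEFAULT_PIXEL_SCALE_UM",
    "feret_diameters",
    "mask_contour",
    "shape_stats",
    "size_category",
]

DEFAULT_PIXEL_SCALE_UM = 18.0

#: Category names in increasing size order.
SIZE_CATEGORIES = ("small", "medium", "large", "extra_large")

#: Half-open pixel boundaries: small <6, medium [6,10), large [10,20),
#: extra_large >=20.  Boundary values go to the larger category.
SIZE_BOUNDS_PX = (6, 10, 20)


@dataclass(frozen=True)
class ShapeStats:
    """Morphometric summary of one particle mask."""

    area_px: int
    perimeter_px: float
    feret_h_px: float
    feret_v_px: float
    feret_max_px: float
    feret_min_px: float
    circularity: float
    aspect_ratio: float
    size_px: int          # feret_max rounded to nearest integer pixel
    size_um: float        # feret_max_px * pixel_scale
    size_category: str


def _hull_points(points: np.ndarray) -> np.ndarray:
    """Convex hull vertices of a point set; falls back to the full set for
    degenerate (collinear) input."""
    try:
        hull = ConvexHull(points)
        return points[hull.vertices]
    except QhullError:
        return points


def _max_caliper(hull: np.ndarray) -> float:
    diff = hull[:, None, :] - hull[None, :, :]
    return float(np.sqrt((diff ** 2).sum(-1)).max())


def _min_caliper(hull: np.ndarray) -> float:
    """Minimum width over directions: attained perpendicular to a hull edge."""
    n = len(hull)
    if n < 3:
        return 0.0
    widths = []
    for i in range(n):
        a, b = hull[i], hull[(i + 1) % n]
        e = b - a
        norm = np.hypot(*e)
        if norm == 0:
            continue
        normal = np.array([-e[1], e[0]]) / norm
        proj = (hull - a) @ normal
        widths.append(proj.max() - proj.min())
    return float(min(widths)) if widths else 0.0


def feret_diameters(contour: np.ndarray) -> tuple[float, float, float, float]:
    """Feret (caliper) diameters of a closed contour.

    Parameters
    ----------
    contour : (N, 2) array of (x, y) vertices, N >= 3.

    Returns
    -------
    (feret_h, feret_v, feret_max, feret_min) :
        horizontal / vertical bounding-box extents, the maximum caliper
        width (longest point-to-point distance) and the minimum caliper
        width.  A degenerate collinear contour reports ``feret_min = 1.0``
        (one-pixel line-width convention).
    """
    pts = np.asarray(contour, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 2:
        raise ValueError("contour must be an (N, 2) array with N >= 3")
    feret_h = float(pts[:, 0].max() - pts[:, 0].min())
    feret_v = float(pts[:, 1].max() - pts[:, 1].min())
    hull = _hull_points(pts)
    feret_max = _max_caliper(hull)
    feret_min = _min_caliper(hull)
    if feret_min == 0.0:  # collinear
        feret_min = 1.0
    return feret_h, feret_v, feret_max, feret_min


def mask_contour(mask: np.ndarray) -> np.ndarray:
    """Outer boundary polygon of a binary mask as (x, y) vertices.

    The contour is traced at iso-level 0.5 on the zero-padded mask, giving
    a closed sub-pixel polygon half a pixel outside the foreground pixel
    centres.  Only the longest (outer) contour is returned.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    padded = np.pad(mask, 1).astype(float)
    contours = _skmeasure.find_contours(padded, 0.5)
    outer = max(contours, key=len)
    # find_contours yields (row, col) = (y, x), offset by the 1-px pad
    xy = np.column_stack([outer[:, 1] - 1.0, outer[:, 0] - 1.0])
    return xy


def _polyline_length(poly: np.ndarray) -> float:
    closed = poly if np.allclose(poly[0], poly[-1]) else np.vstack([poly, poly[0]])
    return float(np.hypot(*np.diff(closed, axis=0).T).sum())


def shape_stats(mask: np.ndarray, pixel_scale: float = DEFAULT_PIXEL_SCALE_UM) -> ShapeStats:
    """Full morphometry of a binary mask.

    Raises ``ValueError`` on an empty mask or non-positive pixel scale.
    """
    if pixel_scale <= 0:
        raise ValueError("pixel_scale must be positive")
    mask = np.asarray(mask).astype(bool)
    area = int(mask.sum())
    if area == 0:
        raise ValueError("empty mask")
    contour = mask_contour(mask)
    perimeter = _polyline_length(contour)
    feret_h, feret_v, feret_max, feret_min = feret_diameters(contour)
    circularity = 4.0 * np.pi * area / perimeter ** 2
    aspect = feret_max / feret_min if feret_min > 0 else float("inf")
    size_px = max(1, int(round(feret_max)))
    size_um = feret_max * pixel_scale
    return ShapeStats(
        area_px=area,
        perimeter_px=perimeter,
        feret_h_px=feret_h,
        feret_v_px=feret_v,
        feret_max_px=feret_max,
        feret_min_px=feret_min,
        circularity=float(circularity),
        aspect_ratio=float(aspect),
        size_px=size_px,
        size_um=float(size_um),
        size_category=size_category(size_px),
    )


def size_category(size: float, pixel_scale: float | None = None) -> str:
    """Size category of a particle.

    ``size`` is in pixels; pass ``pixel_scale`` to categorise a size given
    in micrometres instead (the um boundaries are the pixel boundaries
    times the scale: 108 / 180 / 360 um at 18 um/px).  Sizes are rounded to
    the nearest pixel before categorisation; boundaries belong to the
    larger category (half-open [lower, upper) bins).
    """
    if size <= 0:
        raise ValueError("size must be positive")
    px = size / pixel_scale if pixel_scale is not None else size
    px = int(round(px))
    for bound, name in zip(SIZE_BOUNDS_PX, SIZE_CATEGORIES[:-1]):
        if px < bound:
            return name
    return SIZE_CATEGORIES[-1]
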