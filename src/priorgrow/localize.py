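"""Automatic tumor localization from prior size knowledge.

The tumor candidate is found without any user interaction: the
(contrast-adjusted) slice is binarized with Otsu's threshold, the outer
contour of every connected foreground component is extracted, and each
contour is screened against two priors taken from the TNM T1c-T2b size
cut-points:

* condition a - maximum size (Feret diameter) in (2, 5] cm;
* condition b - enclosed area in (1, 6.25*pi] cm^2, where the floor
  discards thin vessel-tree cross-sections and the cap is the area of the
  5-cm-diameter circle.

A surviving contour is the target contour D; its area centroid
C = (integral of x dA / A, integral of y dA / A) becomes the initial seed
point of the region-growing ensemble.

Physical measurements use corner geometry: a region's boundary is the
outline of its pixel squares, so an m x n pixel rectangle measures a
diagonal of sqrt(m^2 + n^2) px, not (m-1, n-1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage import measure
from skimage.filters import threshold_otsu

from .errors import DegenerateImageError, ValidationError

__all__ = [
    "Contour",
    "PriorBounds",
    "binarize_otsu",
    "extract_contours",
    "max_feret_diameter",
    "filter_candidates",
    "centroid",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)

_CORNER_OFFSETS = np.array(
    [[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]], dtype=np.float64
)


@dataclass
class Contour:
    """Outer boundary of one connected foreground component.

    ``mask`` is the hole-filled component on the full image grid, which is
    what the area, the centroid and the seed sectors are measured on.
    ``polygon`` is the closed outer boundary trace in (row, col) pixel
    coordinates, oriented clockwise in image (row-down) display.
    """

    polygon: np.ndarray
    mask: np.ndarray
    spacing_mm: float
    area_px: int = field(init=False)

    def __post_init__(self):
        self.polygon = np.asarray(self.polygon, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.area_px = int(self.mask.sum())
        if self.area_px <= 0:
            raise ValidationError("contour encloses no pixels")
        if not (self.spacing_mm > 0):
            raise ValidationError("spacing_mm must be > 0")
        self._boundary_px = None
        self._feret_px = None

    @property
    def area_cm2(self) -> float:
        return self.area_px * (self.spacing_mm / 10.0) ** 2

    @property
    def boundary_pixels(self) -> np.ndarray:
        """(N, 2) integer coordinates of mask pixels touching the outside."""
        if self._boundary_px is None:
            eroded = ndimage.binary_erosion(self.mask, structure=_STRUCT8, border_value=0)
            self._boundary_px = np.argwhere(self.mask & ~eroded)
        return self._boundary_px

    @property
    def max_size_px(self) -> float:
        if self._feret_px is None:
            self._feret_px = feret_diameter_px(self.boundary_pixels)
        return self._feret_px

    @property
    def max_size_cm(self) -> float:
        return self.max_size_px * self.spacing_mm / 10.0


@dataclass(frozen=True)
class PriorBounds:
    """Size/area screening windows, strict at the low end, inclusive at the high end."""

    size_low_cm: float = 2.0
    size_high_cm: float = 5.0
    area_low_cm2: float = 1.0
    area_high_cm2: float = 6.25 * math.pi

    def __post_init__(self):
        if not (self.size_low_cm < self.size_high_cm):
            raise ValidationError("size_low_cm must be < size_high_cm")
        if not (self.area_low_cm2 < self.area_high_cm2):
            raise ValidationError("area_low_cm2 must be < area_high_cm2")


def binarize_otsu(image: np.ndarray) -> tuple[np.ndarray, float]:
    """Binarize with the threshold that maximizes between-class variance.

    Returns ``(mask, threshold)`` with ``mask = image > threshold``.
    Raises :class:`DegenerateImageError` for a constant image, whose
    histogram admits no two classes.
    """
    image = np.asarray(image)
    if image.ndim != 2 or image.size == 0:
        raise ValidationError("image must be a non-empty 2-D array")
    if image.min() == image.max():
        raise DegenerateImageError("constant image: Otsu threshold is undefined")
    thr = threshold_otsu(image)
    return image > thr, float(thr)


def _orient_clockwise(polygon: np.ndarray) -> np.ndarray:
    # shoelace in (row, col); row grows downward, so screen-clockwise means
    # positive signed area in (x=col, y=row) axes
    r, c = polygon[:-1, 0], polygon[:-1, 1]
    r2, c2 = polygon[1:, 0], polygon[1:, 1]
    signed = float(np.sum(c * r2 - c2 * r)) / 2.0
    return polygon if signed >= 0 else polygon[::-1]


def trace_outer_boundary(mask: np.ndarray) -> np.ndarray:
    """Closed clockwise outer boundary polygon of a binary region."""
    padded = np.pad(mask.astype(float), 1)
    traces = measure.find_contours(padded, 0.5)
    if not traces:
        raise ValidationError("cannot trace boundary of an empty mask")
    poly = max(traces, key=len) - 1.0
    if not np.allclose(poly[0], poly[-1]):
        poly = np.vstack([poly, poly[:1]])
    return _orient_clockwise(poly)


def extract_contours(binary: np.ndarray, spacing_mm: float) -> list[Contour]:
    """Outer contour of every 8-connected foreground component.

    Holes are ignored: each component is hole-filled before its area is
    counted, so ``area_px`` is the enclosed pixel count. Components are
    returned in raster (label) order.
    """
    binary = np.asarray(binary).astype(bool)
    labels, n = ndimage.label(binary, structure=_STRUCT8)
    contours: list[Contour] = []
    for lbl in range(1, n + 1):
        comp = labels == lbl
        filled = ndimage.binary_fill_holes(comp)
        contours.append(Contour(trace_outer_boundary(filled), filled, spacing_mm))
    return contours


def feret_diameter_px(boundary_pixels: np.ndarray) -> float:
    """Maximum caliper width of a region, in pixels.

    Each boundary pixel contributes the four corners of its unit square;
    the answer is the largest pairwise distance among those corners
    (computed on the convex hull).  A single-pixel region degenerates to 0.
    """
    pts = np.asarray(boundary_pixels, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[0] == 0:
        raise ValidationError("boundary_pixels must be a non-empty (N, 2) array")
    if pts.shape[0] == 1:
        return 0.0
    corners = (pts[:, None, :] + _CORNER_OFFSETS[None, :, :]).reshape(-1, 2)
    corners = np.unique(corners, axis=0)
    try:
        hull_pts = corners[ConvexHull(corners).vertices]
    except QhullError:
        hull_pts = corners
    diff = hull_pts[:, None, :] - hull_pts[None, :, :]
    return float(np.sqrt((diff**2).sum(-1)).max())


def max_feret_diameter(contour: Contour) -> float:
    """Maximum size of a contour (longest caliper) in centimetres."""
    if contour.area_px == 1:
        return 0.0
    return contour.max_size_cm


def filter_candidates(contours: list[Contour], bounds: PriorBounds = PriorBounds()) -> list[Contour]:
    """Keep contours satisfying both prior conditions (a: size, b: area).

    Pure filter: the result is a subsequence of the input and applying it
    twice equals applying it once.
    """
    out = []
    for ct in contours:
        size_ok = bounds.size_low_cm < ct.max_size_cm <= bounds.size_high_cm
        area_ok = bounds.area_low_cm2 < ct.area_cm2 <= bounds.area_high_cm2
        if size_ok and area_ok:
            out.append(ct)
    return out


def centroid(contour: Contour) -> tuple[float, float]:
    """Area centroid of the filled contour region, fractional (row, col).

    Equals the first moments over the enclosed region divided by its area,
    i.e. the mean coordinate of the enclosed pixels. Round to the nearest
    integer pixel to obtain the initial seed point.
    """
    if contour.area_px <= 0:
        raise ValidationError("centroid of a zero-area contour is undefined")
    rows, cols = np.nonzero(contour.mask)
    return float(rows.mean()), float(cols.mean())
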