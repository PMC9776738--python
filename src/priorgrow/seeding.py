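"""Seed-point expansion: from the centroid seed p1 to the ensemble p1..p7.

Three dividing lines through the centroid C, mutually at 60 degrees, split
the filled target region into six angular sectors; the pixel centroid of
each sector is an additional seed.  A sector centroid that falls outside
the region (concave tumors) is replaced by the midpoint of the shortest
line from C to the region boundary within that sector, so every seed is
guaranteed to lie on tumor tissue.

Angles are measured from the image row axis (0 degrees points down-image),
and sector membership uses half-open intervals [theta, theta + 60), which
makes the six sectors an exact partition of the region's pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .localize import Contour

__all__ = ["SeedSet", "expand_seeds", "fallback_seed", "sector_index"]

Point = tuple[int, int]


@dataclass
class SeedSet:
    """The ensemble's seven seed points.

    ``p1`` is the prior-derived centroid seed; ``extras`` are the six
    sector seeds p2..p7 (fewer only if a sector contained no region
    pixels, which is flagged).  ``flags`` maps sector index (0-5) or -1
    (whole set) to a note about fallbacks taken.
    """

    p1: Point
    extras: list[Point]
    sector_angles: tuple[float, float, float] = (0.0, 60.0, 120.0)
    flags: dict[int, str] = field(default_factory=dict)

    @property
    def seeds(self) -> list[Point]:
        return [self.p1] + list(self.extras)

    def __len__(self) -> int:
        return 1 + len(self.extras)


def sector_index(drow: np.ndarray, dcol: np.ndarray, offset_deg: float = 0.0) -> np.ndarray:
    """Sector number (0-5) of displacement vectors from the centroid."""
    theta = np.degrees(np.arctan2(dcol, drow))
    return (np.floor(((theta - offset_deg) % 360.0) / 60.0).astype(int)) % 6


def _in_region(mask: np.ndarray, p: Point) -> bool:
    r, c = p
    return 0 <= r < mask.shape[0] and 0 <= c < mask.shape[1] and bool(mask[r, c])


def _nearest_region_pixel(region_pts: np.ndarray, target: Point, exclude: set[Point]) -> Point:
    d2 = (region_pts[:, 0] - target[0]) ** 2 + (region_pts[:, 1] - target[1]) ** 2
    for idx in np.argsort(d2, kind="stable"):
        cand = (int(region_pts[idx, 0]), int(region_pts[idx, 1]))
        if cand not in exclude:
            return cand
    raise ValidationError("region has no free pixel left for a distinct seed")


def fallback_seed(
    contour: Contour, c: Point, sector: tuple[float, float], offset_deg: float = 0.0
) -> Point:
    """Replacement seed for a sector whose centroid left the region.

    Returns the midpoint of the shortest segment from C to the region
    boundary restricted to the sector; if that midpoint is itself outside
    the region (deep concavity), the nearest region pixel to it is used.
    """
    bpx = contour.boundary_pixels
    sec = sector_index(bpx[:, 0] - c[0], bpx[:, 1] - c[1], offset_deg)
    k = int(round(((sector[0] - offset_deg) % 360.0) / 60.0)) % 6
    in_sec = bpx[sec == k]
    if in_sec.size == 0:
        raise ValidationError(f"sector {k} contains no boundary pixels")
    d2 = (in_sec[:, 0] - c[0]) ** 2 + (in_sec[:, 1] - c[1]) ** 2
    b = in_sec[int(np.argmin(d2))]
    mid = (int(round((c[0] + b[0]) / 2.0)), int(round((c[1] + b[1]) / 2.0)))
    if _in_region(contour.mask, mid):
        return mid
    region_pts = np.argwhere(contour.mask)
    return _nearest_region_pixel(region_pts, mid, exclude=set())


def expand_seeds(contour: Contour, c: Point, sector_offset_deg: float = 0.0) -> SeedSet:
    """Expand the centroid seed into the full seven-seed ensemble.

    ``c`` must lie inside the filled target region.  Regions smaller than
    seven pixels cannot host seven distinct seeds; they degenerate to p1
    repeated six times (flagged).
    """
    mask = contour.mask
    c = (int(c[0]), int(c[1]))
    if not _in_region(mask, c):
        raise ValidationError(f"seed point {c} is not inside the target region")

    region_pts = np.argwhere(mask)
    angles = (
        sector_offset_deg % 360.0,
        (sector_offset_deg + 60.0) % 360.0,
        (sector_offset_deg + 120.0) % 360.0,
    )
    if region_pts.shape[0] < 7:
        return SeedSet(c, [c] * 6, angles, flags={-1: "degenerate: region smaller than 7 px"})

    sec = sector_index(region_pts[:, 0] - c[0], region_pts[:, 1] - c[1], sector_offset_deg)
    extras: list[Point] = []
    flags: dict[int, str] = {}
    used: set[Point] = {c}
    for k in range(6):
        pts = region_pts[sec == k]
        if pts.shape[0] == 0:
            flags[k] = "omitted: sector contains no region pixels"
            continue
        cand = (int(round(pts[:, 0].mean())), int(round(pts[:, 1].mean())))
        if not _in_region(mask, cand):
            lo = (sector_offset_deg + 60.0 * k) % 360.0
            cand = fallback_seed(contour, c, (lo, lo + 60.0), sector_offset_deg)
            flags[k] = "fallback: sector centroid outside region"
        if cand in used:
            cand = _nearest_region_pixel(pts, cand, used)
            flags[k] = flags.get(k, "") + " nudged-to-distinct"
        used.add(cand)
        extras.append(cand)
    return SeedSet(c, extras, angles, flags)
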