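"""The segmentation engine: seeded region growing with prior restrictions.

Each seed grows by breadth-first absorption of neighboring pixels whose
intensity lies within a tolerance of the seed's own intensity (the "base
value", fixed for the whole growth).  The tolerance starts at a fraction
(default 20%) of the whole image's intensity range; for every subsequent
seed it is refreshed from a circular neighborhood of the previous seed --
radius L = (max distance from that seed to its grown boundary) + a margin
(default 6 px) -- so the tolerance adapts to the local tumor/parenchyma
contrast as the ensemble walks across the lesion.

Every grown region is screened by a growth-restriction check before it may
contribute to the final result: with a user-predicted maximum tumor size,
the region's Feret diameter must not exceed it; without one, the region's
area must not exceed the circle circumscribed about the target contour D
(radius = farthest boundary point from the centroid C).  Regions failing
the check are "abnormal" and are discarded whole; the final segmentation
is the union of the credible regions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import AllRegionsAbnormalError, LocalizationError, ValidationError
from .image_io import CTSlice, PerSeedEntry, SegmentationReport
from .localize import (
    Contour,
    PriorBounds,
    binarize_otsu,
    centroid,
    extract_contours,
    feret_diameter_px,
    filter_candidates,
    trace_outer_boundary,
)
from .preprocess import PreprocessParams, adjust_contrast
from .seeding import SeedSet, expand_seeds

__all__ = [
    "GrowthParams",
    "GrownRegion",
    "SegmentationResult",
    "compute_initial_threshold",
    "grow_region",
    "update_threshold",
    "check_credible",
    "combine",
    "segment_candidate",
    "segment_all_candidates",
    "segment_tumor",
    "grow_manual",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)
_STRUCT4 = ndimage.generate_binary_structure(2, 1)


@dataclass(frozen=True)
class GrowthParams:
    """Knobs of the growing engine.

    threshold_frac
        Fraction of the reference intensity range used as the growth
        tolerance (whole image for p1, the local circle thereafter).
    margin_px
        Extra pixels added to the radius L of the threshold-update circle.
    connectivity
        4 or 8 (8 matches the contour extraction and is the default).
    predicted_max_size_cm
        Optional clinician-supplied cap on tumor size; switches the
        credibility check from circle-area mode to predicted-size mode.
    anchor_p1
        If True, every threshold update circles around p1 instead of
        chaining through the previous seed.
    sector_offset_deg
        Rotation of the three seed-expansion dividing lines.
    """

    threshold_frac: float = 0.2
    margin_px: float = 6.0
    connectivity: int = 8
    predicted_max_size_cm: Optional[float] = None
    anchor_p1: bool = False
    sector_offset_deg: float = 0.0

    def __post_init__(self):
        if not (0.0 < self.threshold_frac < 1.0):
            raise ValidationError("threshold_frac must lie in (0, 1)")
        if self.margin_px < 0:
            raise ValidationError("margin_px must be >= 0")
        if self.connectivity not in (4, 8):
            raise ValidationError("connectivity must be 4 or 8")


@dataclass
class GrownRegion:
    """Result of growing one seed."""

    seed: tuple[int, int]
    base_intensity: float
    threshold: float
    mask: np.ndarray
    spacing_mm: float = 1.0
    credible: bool = True

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        self._feret_px: Optional[float] = None

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    @property
    def boundary_pixels(self) -> np.ndarray:
        eroded = ndimage.binary_erosion(self.mask, structure=_STRUCT8, border_value=0)
        return np.argwhere(self.mask & ~eroded)

    @property
    def max_size_px(self) -> float:
        if self._feret_px is None:
            bp = self.boundary_pixels
            self._feret_px = 0.0 if bp.shape[0] <= 1 else feret_diameter_px(bp)
        return self._feret_px

    @property
    def max_size_cm(self) -> float:
        return self.max_size_px * self.spacing_mm / 10.0


@dataclass
class SegmentationResult:
    """Per-candidate outcome of the full ensemble segmentation."""

    regions: list[GrownRegion]
    combined_mask: np.ndarray
    boundary: np.ndarray
    restriction_mode: str
    contour: Optional[Contour] = None
    seed_set: Optional[SeedSet] = None
    notes: dict = field(default_factory=dict)

    @property
    def combined_area_px(self) -> int:
        return int(np.asarray(self.combined_mask).sum())

    def to_report(self, dice: Optional[float] = None, jaccard_distance: Optional[float] = None) -> SegmentationReport:
        entries = [
            PerSeedEntry(
                seed=r.seed,
                threshold=float(r.threshold),
                area_px=r.area_px,
                max_size_px=float(r.max_size_px),
                credible=bool(r.credible),
            )
            for r in self.regions
        ]
        return SegmentationReport(
            per_seed_entries=entries,
            combined_area_px=self.combined_area_px,
            boundary_polygon=[(float(r), float(c)) for r, c in np.asarray(self.boundary)],
            restriction_mode=self.restriction_mode,
            dice=dice,
            jaccard_distance=jaccard_distance,
            notes=dict(self.notes),
        )


def compute_initial_threshold(image: np.ndarray, frac: float = 0.2) -> float:
    """Growth tolerance for the first seed: frac x (max - min) of the image."""
    image = np.asarray(image)
    rng = float(image.max()) - float(image.min())
    if rng == 0.0:
        warnings.warn("constant image: growth tolerance is 0", stacklevel=2)
    return float(frac) * rng


def grow_region(
    image: np.ndarray,
    seed: tuple[int, int],
    threshold: float,
    connectivity: int = 8,
    spacing_mm: float = 1.0,
) -> GrownRegion:
    """Breadth-first region growing from one seed.

    A pixel joins the region iff it is connected to the seed through pixels
    whose intensity differs from the SEED's intensity (the base value, not a
    running mean) by at most ``threshold``.  Equivalent to taking the seed's
    connected component of the predicate ``|I - base| <= threshold``; growth
    stops when no new growth point exists, and the outermost pixels of the
    grown set are the segmented boundary.
    """
    image = np.asarray(image)
    r, c = int(seed[0]), int(seed[1])
    if not (0 <= r < image.shape[0] and 0 <= c < image.shape[1]):
        raise ValidationError(f"seed {seed} lies outside the image {image.shape}")
    base = float(image[r, c])
    predicate = np.abs(image.astype(np.float64) - base) <= float(threshold)
    structure = _STRUCT8 if connectivity == 8 else _STRUCT4
    labels, _ = ndimage.label(predicate, structure=structure)
    mask = labels == labels[r, c]
    return GrownRegion((r, c), base, float(threshold), mask, spacing_mm)


def update_threshold(
    image: np.ndarray,
    prev_seed: tuple[int, int],
    prev_region: GrownRegion,
    frac: float = 0.2,
    margin_px: float = 6.0,
) -> float:
    """Refresh the growth tolerance from a circle around the previous seed.

    The circle's radius L is the maximum distance from ``prev_seed`` to the
    previous grown region's boundary pixels plus ``margin_px``; the new
    tolerance is ``frac`` x (max - min) of the intensities inside the circle
    (clipped to the image).  An empty previous region falls back to the
    whole-image tolerance with a warning.
    """
    image = np.asarray(image)
    bp = prev_region.boundary_pixels
    if bp.shape[0] == 0:
        warnings.warn("empty previous region: falling back to whole-image tolerance", stacklevel=2)
        return compute_initial_threshold(image, frac)
    sr, sc = float(prev_seed[0]), float(prev_seed[1])
    dist = np.sqrt((bp[:, 0] - sr) ** 2 + (bp[:, 1] - sc) ** 2)
    radius = float(dist.max()) + float(margin_px)
    rr, cc = np.ogrid[: image.shape[0], : image.shape[1]]
    disk = (rr - sr) ** 2 + (cc - sc) ** 2 <= radius**2
    roi = image[disk]
    rng = float(roi.max()) - float(roi.min())
    if rng == 0.0:
        warnings.warn("constant intensities inside the update circle: tolerance is 0", stacklevel=2)
    return float(frac) * rng


def restriction_radius_px(contour_d: Contour, c: tuple[float, float]) -> float:
    """Longest distance from the centroid C to the target contour's boundary.

    Measured to the corners of the boundary pixels' unit squares (the true
    outline of the region), so the region's pixel area can never exceed the
    area of its own restriction circle.
    """
    bp = contour_d.boundary_pixels.astype(np.float64)
    dr = np.maximum(np.abs(bp[:, 0] - c[0] - 0.5), np.abs(bp[:, 0] - c[0] + 0.5))
    dc = np.maximum(np.abs(bp[:, 1] - c[1] - 0.5), np.abs(bp[:, 1] - c[1] + 0.5))
    return float(np.sqrt(dr**2 + dc**2).max())


def check_credible(
    region: GrownRegion,
    contour_d: Optional[Contour],
    c: Optional[tuple[float, float]],
    params: GrowthParams,
) -> bool:
    """Growth-restriction screen deciding credible vs abnormal.

    Predicted-size mode: the grown region's maximum size (cm) must not
    exceed the predicted maximum tumor size.  Circle mode (no prediction):
    the region's pixel area must not exceed the area of the circle whose
    radius is the farthest distance from C to the contour D boundary.
    """
    if params.predicted_max_size_cm is not None:
        return region.max_size_cm <= params.predicted_max_size_cm
    if contour_d is None or c is None:
        raise ValidationError(
            "circle-mode credibility needs the target contour and centroid"
        )
    radius = restriction_radius_px(contour_d, c)
    return region.area_px <= math.pi * radius**2


def combine(regions: list[GrownRegion]) -> tuple[np.ndarray, np.ndarray]:
    """Union of the credible regions' masks and its outer boundary polygon.

    Raises :class:`AllRegionsAbnormalError` (with per-seed diagnostics)
    when no region passed its credibility check -- there is deliberately
    no silent fallback.
    """
    if not regions:
        raise ValidationError("combine requires at least one grown region")
    credible = [r for r in regions if r.credible]
    if not credible:
        diag = [
            {"seed": r.seed, "area_px": r.area_px, "max_size_px": r.max_size_px}
            for r in regions
        ]
        raise AllRegionsAbnormalError(
            "all grown regions failed the growth-restriction check", diagnostics=diag
        )
    mask = np.zeros_like(credible[0].mask, dtype=bool)
    for r in credible:
        mask |= r.mask
    return mask, trace_outer_boundary(mask)


def segment_candidate(
    ct: CTSlice,
    contour_d: Contour,
    params: GrowthParams = GrowthParams(),
) -> SegmentationResult:
    """Run the seven-seed ensemble on one localized candidate contour.

    Growth always happens on the ORIGINAL slice intensities (the
    contrast-stretched copy is only used upstream for localization).
    """
    cen = centroid(contour_d)
    c = (int(round(cen[0])), int(round(cen[1])))
    if not contour_d.mask[c]:
        # concave region whose area centroid falls outside the tissue:
        # snap to the nearest region pixel so that p1 is a valid seed
        pts = np.argwhere(contour_d.mask)
        d2 = (pts[:, 0] - cen[0]) ** 2 + (pts[:, 1] - cen[1]) ** 2
        c = tuple(int(v) for v in pts[int(np.argmin(d2))])
    seed_set = expand_seeds(contour_d, c, params.sector_offset_deg)

    image = ct.pixels
    threshold = compute_initial_threshold(image, params.threshold_frac)
    regions: list[GrownRegion] = []
    for i, seed in enumerate(seed_set.seeds):
        if i > 0:
            anchor = regions[0] if params.anchor_p1 else regions[-1]
            threshold = update_threshold(
                image, anchor.seed, anchor, params.threshold_frac, params.margin_px
            )
        region = grow_region(image, seed, threshold, params.connectivity, ct.spacing_mm)
        region.credible = check_credible(region, contour_d, c, params)
        regions.append(region)

    mode = "predicted-size" if params.predicted_max_size_cm is not None else "circle-area"
    mask, boundary = combine(regions)
    notes = {"seed_flags": {str(k): v for k, v in seed_set.flags.items()}} if seed_set.flags else {}
    return SegmentationResult(regions, mask, boundary, mode, contour_d, seed_set, notes)


def segment_all_candidates(
    ct: CTSlice,
    params: GrowthParams = GrowthParams(),
    preproc: PreprocessParams = PreprocessParams(),
    bounds: PriorBounds = PriorBounds(),
) -> list[SegmentationResult]:
    """Full automatic workflow, one result per surviving candidate contour.

    Steps: contrast-adjust -> Otsu binarize -> extract contours -> prior
    filter -> (per candidate) centroid seed -> seed expansion -> chained
    threshold growing -> credibility screen -> combination.  Candidates
    are returned in decreasing area order, so the first is the primary.
    """
    stretched = adjust_contrast(ct, preproc)
    binary, _ = binarize_otsu(stretched.pixels)
    contours = extract_contours(binary, ct.spacing_mm)
    candidates = filter_candidates(contours, bounds)
    if not candidates:
        raise LocalizationError(
            "no contour satisfies the prior size/area conditions "
            f"(size in ({bounds.size_low_cm}, {bounds.size_high_cm}] cm, area in "
            f"({bounds.area_low_cm2}, {bounds.area_high_cm2:.2f}] cm^2); "
            "the tumor may be outside the 2-5 cm range -- supply a manual seed point"
        )
    candidates = sorted(candidates, key=lambda ct_: ct_.area_px, reverse=True)
    return [segment_candidate(ct, cand, params) for cand in candidates]


def segment_tumor(
    ct: CTSlice,
    params: GrowthParams = GrowthParams(),
    preproc: PreprocessParams = PreprocessParams(),
    bounds: PriorBounds = PriorBounds(),
) -> SegmentationResult:
    """Automatic segmentation of the primary (largest-area) candidate."""
    return segment_all_candidates(ct, params, preproc, bounds)[0]


def grow_manual(
    ct: CTSlice,
    seed: tuple[int, int],
    params: GrowthParams = GrowthParams(),
) -> SegmentationResult:
    """Single-seed segmentation from a manually supplied seed point.

    Bypasses localization (the documented fallback when the tumor size is
    outside the prior window).  Without a target contour there is no sector
    geometry and no restriction circle, so the region is grown once with
    the whole-image tolerance; credibility is checked only when a predicted
    maximum size is given.
    """
    threshold = compute_initial_threshold(ct.pixels, params.threshold_frac)
    region = grow_region(ct.pixels, seed, threshold, params.connectivity, ct.spacing_mm)
    if params.predicted_max_size_cm is not None:
        region.credible = region.max_size_cm <= params.predicted_max_size_cm
        mode = "predicted-size"
    else:
        mode = "unrestricted-manual"
    mask, boundary = combine([region])
    return SegmentationResult([region], mask, boundary, mode, None, None, {"manual_seed": True})
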