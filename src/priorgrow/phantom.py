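"""Synthetic 2-D chest-CT phantoms with known tumor ground truth.

The phantom emulates the features of an axial lung slice that the
segmentation pipeline actually interacts with: a dark exterior, a
soft-tissue body ellipse, two dark lung fields (lung parenchyma is mostly
air, so its default intensity sits near the exterior), a brighter tumor
blob of controlled physical diameter inside one lung, and thin bright
vessel-like distractors inside the other.  Vessels are drawn short and
thin on purpose: their contours have maximum sizes that can fall inside
the 2-5 cm prior window while their areas stay below the 1 cm^2 floor,
which is precisely the case that floor exists to reject.

Everything is deterministic given ``rng_seed``.  The ground-truth mask
marks exactly the rendered tumor pixels (before noise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage import draw

from .errors import ValidationError
from .image_io import CTSlice

__all__ = ["PhantomSpec", "Phantom", "generate_phantom", "generate_suite"]

_SHAPES = ("disk", "ellipse", "concave-crescent")


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters of one synthetic slice.

    Intensities are 8-bit gray values chosen so that the tumor/lung
    contrast comfortably exceeds the 20% growth tolerance.  ``tumor_center``
    defaults to the center of the right lung (image left).  ``extra_blobs``
    adds further tumor-like blobs as (row, col, diameter_cm) triples, for
    multi-candidate scenarios.
    """

    shape_px: tuple[int, int] = (512, 512)
    spacing_mm: float = 0.7
    tumor_diameter_cm: float = 3.0
    tumor_shape: str = "disk"
    tumor_intensity: int = 200
    lung_intensity: int = 35
    body_intensity: int = 120
    background_intensity: int = 0
    vessel_count: int = 3
    noise_sd: float = 0.0
    rng_seed: int = 0
    tumor_center: Optional[tuple[int, int]] = None
    extra_blobs: tuple[tuple[int, int, float], ...] = ()

    def __post_init__(self):
        shape = self.tumor_shape if self.tumor_shape != "concave" else "concave-crescent"
        object.__setattr__(self, "tumor_shape", shape)
        if shape not in _SHAPES:
            raise ValidationError(f"tumor_shape must be one of {_SHAPES}")
        if not (self.spacing_mm > 0 and self.tumor_diameter_cm > 0):
            raise ValidationError("spacing_mm and tumor_diameter_cm must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")

    def to_dict(self) -> dict:
        return {
            "shape_px": list(self.shape_px),
            "spacing_mm": self.spacing_mm,
            "tumor_diameter_cm": self.tumor_diameter_cm,
            "tumor_shape": self.tumor_shape,
            "tumor_intensity": self.tumor_intensity,
            "lung_intensity": self.lung_intensity,
            "body_intensity": self.body_intensity,
            "background_intensity": self.background_intensity,
            "vessel_count": self.vessel_count,
            "noise_sd": self.noise_sd,
            "rng_seed": self.rng_seed,
            "tumor_center": list(self.tumor_center) if self.tumor_center else None,
            "extra_blobs": [list(b) for b in self.extra_blobs],
        }


@dataclass
class Phantom:
    """A generated slice plus its ground truth and provenance."""

    slice: CTSlice
    truth_mask: np.ndarray
    spec: PhantomSpec
    extra_truths: list[np.ndarray] = field(default_factory=list)
    lung_masks: tuple[np.ndarray, np.ndarray] | None = None
    vessel_mask: np.ndarray | None = None


def _anatomy(shape: tuple[int, int]):
    """Body ellipse and the two lung ellipses, scaled to the frame."""
    h, w = shape
    cr, cc = h / 2.0, w / 2.0
    body = draw.ellipse(cr, cc, 0.46 * h, 0.48 * w, shape=shape)
    lung_r, lung_c = 0.235 * h, 0.137 * w
    right = draw.ellipse(cr, cc - 0.235 * w, lung_r, lung_c, shape=shape)  # image left
    left = draw.ellipse(cr, cc + 0.235 * w, lung_r, lung_c, shape=shape)  # image right
    masks = []
    for rr, cc_ in (body, right, left):
        m = np.zeros(shape, dtype=bool)
        m[rr, cc_] = True
        masks.append(m)
    return masks[0], masks[1], masks[2]


def _render_blob(
    shape: tuple[int, int],
    center: tuple[float, float],
    diameter_cm: float,
    spacing_mm: float,
    blob_shape: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Binary mask of one tumor blob; ``diameter_cm`` is its longest axis."""
    radius = diameter_cm * 10.0 / spacing_mm / 2.0
    mask = np.zeros(shape, dtype=bool)
    cr, cc = center
    if blob_shape == "disk":
        rr, cc_ = draw.disk((cr, cc), radius, shape=shape)
        mask[rr, cc_] = True
    elif blob_shape == "ellipse":
        angle = float(rng.uniform(0.0, math.pi))
        rr, cc_ = draw.ellipse(cr, cc, radius, 0.65 * radius, rotation=angle, shape=shape)
        mask[rr, cc_] = True
    else:  # concave-crescent: disk minus an off-center bite
        rr, cc_ = draw.disk((cr, cc), radius, shape=shape)
        mask[rr, cc_] = True
        phi = float(rng.uniform(0.0, 2.0 * math.pi))
        bite_center = (cr + 0.85 * radius * math.cos(phi), cc + 0.85 * radius * math.sin(phi))
        rr, cc_ = draw.disk(bite_center, 0.55 * radius, shape=shape)
        bite = np.zeros(shape, dtype=bool)
        bite[rr, cc_] = True
        mask &= ~bite
    return mask


def _render_vessels(
    lung: np.ndarray,
    avoid: np.ndarray,
    count: int,
    spacing_mm: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Thin bright polyline distractors, one per disjoint row band of the lung.

    Each segment is 3 px wide and short enough that its pixel area stays
    below ~0.9 x 1 cm^2 at the given spacing; row bands keep segments from
    merging into one large contour.
    """
    vessels = np.zeros_like(lung)
    if count <= 0:
        return vessels
    rows = np.nonzero(lung.any(axis=1))[0]
    if rows.size == 0:
        return vessels
    interior = ndimage.binary_erosion(lung, iterations=4) & ~ndimage.binary_dilation(avoid, iterations=5)
    area_cap_px = 0.9 * (10.0 / spacing_mm) ** 2
    max_len = max(12, min(55, int(area_cap_px / 3.0) - 10))
    r0, r1 = rows[0], rows[-1]
    band_edges = np.linspace(r0, r1 + 1, count + 1).astype(int)
    for k in range(count):
        lo, hi = band_edges[k] + 4, band_edges[k + 1] - 4
        if hi - lo < 8:
            continue
        band = np.zeros_like(lung)
        band[lo:hi, :] = True
        allowed = interior & band
        pts = np.argwhere(allowed)
        if pts.shape[0] == 0:
            continue
        start = pts[int(rng.integers(pts.shape[0]))]
        angle = float(rng.uniform(0.0, math.pi))
        length = float(rng.uniform(0.6 * max_len, max_len))
        end = (
            int(round(start[0] + length * math.cos(angle))),
            int(round(start[1] + length * math.sin(angle))),
        )
        end = (int(np.clip(end[0], lo, hi - 1)), int(np.clip(end[1], 0, lung.shape[1] - 1)))
        seg = np.zeros_like(lung)
        rr, cc = draw.line(int(start[0]), int(start[1]), end[0], end[1])
        seg[rr, cc] = True
        seg = ndimage.binary_dilation(seg, structure=np.ones((3, 3), dtype=bool))
        vessels |= seg & allowed
    return vessels


def generate_phantom(spec: PhantomSpec = PhantomSpec()) -> Phantom:
    """Render one synthetic slice with its ground-truth tumor mask.

    Raises :class:`ValidationError` if the requested tumor does not fit
    inside its lung field.  Identical specs produce bit-identical output.
    """
    rng = np.random.default_rng(spec.rng_seed)
    shape = tuple(spec.shape_px)
    body, right_lung, left_lung = _anatomy(shape)

    img = np.full(shape, spec.background_intensity, dtype=np.float64)
    img[body] = spec.body_intensity
    img[right_lung] = spec.lung_intensity
    img[left_lung] = spec.lung_intensity

    h, w = shape
    center = spec.tumor_center or (int(round(h / 2.0)), int(round(w / 2.0 - 0.235 * w)))
    tumor = _render_blob(shape, center, spec.tumor_diameter_cm, spec.spacing_mm, spec.tumor_shape, rng)
    host = right_lung if right_lung[center] else left_lung
    if not host[center] or not np.all(host[tumor]):
        raise ValidationError(
            f"tumor (diameter {spec.tumor_diameter_cm} cm at {center}) does not fit "
            "inside a lung field"
        )
    img[tumor] = spec.tumor_intensity

    extra_truths: list[np.ndarray] = []
    occupied = tumor.copy()
    for row, col, dia in spec.extra_blobs:
        blob = _render_blob(shape, (row, col), dia, spec.spacing_mm, "disk", rng)
        blob_host = right_lung if right_lung[int(row), int(col)] else left_lung
        if not np.all(blob_host[blob]) or (ndimage.binary_dilation(blob, iterations=3) & occupied).any():
            raise ValidationError(f"extra blob at ({row}, {col}) does not fit or overlaps")
        img[blob] = spec.tumor_intensity
        extra_truths.append(blob)
        occupied |= blob

    vessel_lung = left_lung if host is right_lung else right_lung
    vessels = _render_vessels(vessel_lung, occupied, spec.vessel_count, spec.spacing_mm, rng)
    img[vessels] = spec.tumor_intensity

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    ct = CTSlice(img, spec.spacing_mm, source_path=f"phantom(seed={spec.rng_seed})", bit_depth=8)
    return Phantom(ct, tumor, spec, extra_truths, (right_lung, left_lung), vessels)


def generate_suite(
    n: int,
    base_spec: PhantomSpec = PhantomSpec(),
    seed: int = 0,
    diameter_range_cm: tuple[float, float] = (2.2, 4.8),
    noise_sd_max: float = 10.0,
    shapes: Sequence[str] = _SHAPES,
) -> list[Phantom]:
    """A reproducible batch of phantoms with varied size, shape, and noise.

    Diameters are sampled uniformly over ``diameter_range_cm`` (inside the
    2-5 cm prior window by default), shapes cycle through ``shapes``, and
    the noise standard deviation is uniform on [0, ``noise_sd_max``] gray
    levels.  The same ``seed`` always yields the identical suite.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        spec = replace(
            base_spec,
            tumor_diameter_cm=float(rng.uniform(*diameter_range_cm)),
            tumor_shape=shapes[i % len(shapes)],
            noise_sd=float(rng.uniform(0.0, noise_sd_max)),
            rng_seed=int(rng.integers(0, 2**31)),
        )
        out.append(generate_phantom(spec))
    return out
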