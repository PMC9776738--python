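"""Reading CT slices and writing segmentation artifacts.

A CT slice is a single 2-D grayscale array with an isotropic physical pixel
spacing in millimetres.  DICOM files carry the spacing in their PixelSpacing
tag; for PNG/TIFF inputs the caller must supply it, because every prior bound
used for tumor localization is stated in centimetres and is converted to
pixels through this spacing (cm = px * spacing_mm / 10).

Intensities are never rescaled on input: the 20% threshold rule of the
growing engine is relative to the observed intensity range, so no HU
calibration or windowing is required.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pydicom

from .errors import ConfigurationError, ValidationError

__all__ = [
    "CTSlice",
    "SegmentationReport",
    "PerSeedEntry",
    "read_ct_slice",
    "read_mask",
    "write_mask",
    "write_report",
    "read_report",
]

_DICOM_SUFFIXES = {".dcm", ".dicom", ".ima"}


@dataclass
class CTSlice:
    """One 2-D grayscale CT slice plus its physical pixel spacing.

    Attributes
    ----------
    pixels : numpy.ndarray
        2-D array of gray intensities (rows x cols), native bit depth.
    spacing_mm : float
        Millimetres per pixel, isotropic.
    source_path : str
        Provenance of the data (file path or a synthetic-origin tag).
    bit_depth : int
        Bits per stored sample.
    """

    pixels: np.ndarray
    spacing_mm: float
    source_path: str = ""
    bit_depth: int = 8

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValidationError("pixels must be a non-empty 2-D array")
        if not np.all(np.isfinite(np.asarray(self.pixels, dtype=float))):
            raise ValidationError("pixel intensities must be finite")
        if not (float(self.spacing_mm) > 0):
            raise ValidationError(f"spacing_mm must be > 0, got {self.spacing_mm!r}")
        self.spacing_mm = float(self.spacing_mm)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class PerSeedEntry:
    """Audit record for one seed of the ensemble."""

    seed: tuple[int, int]
    threshold: float
    area_px: int
    max_size_px: float
    credible: bool


@dataclass
class SegmentationReport:
    """Serializable summary of a segmentation run.

    ``dice`` and ``jaccard_distance`` are present only when a ground-truth
    mask was supplied for evaluation.
    """

    per_seed_entries: list[PerSeedEntry]
    combined_area_px: int
    boundary_polygon: list[tuple[float, float]]
    restriction_mode: str = "circle-area"
    dice: Optional[float] = None
    jaccard_distance: Optional[float] = None
    notes: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "per_seed_entries": [
                {
                    "seed": [int(e.seed[0]), int(e.seed[1])],
                    "threshold": float(e.threshold),
                    "area_px": int(e.area_px),
                    "max_size_px": float(e.max_size_px),
                    "credible": bool(e.credible),
                }
                for e in self.per_seed_entries
            ],
            "combined_area_px": int(self.combined_area_px),
            "boundary_polygon": [[float(r), float(c)] for r, c in self.boundary_polygon],
            "restriction_mode": self.restriction_mode,
        }
        if self.dice is not None:
            d["dice"] = float(self.dice)
        if self.jaccard_distance is not None:
            d["jaccard_distance"] = float(self.jaccard_distance)
        if self.notes:
            d["notes"] = self.notes
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SegmentationReport":
        entries = [
            PerSeedEntry(
                seed=(int(e["seed"][0]), int(e["seed"][1])),
                threshold=float(e["threshold"]),
                area_px=int(e["area_px"]),
                max_size_px=float(e["max_size_px"]),
                credible=bool(e["credible"]),
            )
            for e in d["per_seed_entries"]
        ]
        return cls(
            per_seed_entries=entries,
            combined_area_px=int(d["combined_area_px"]),
            boundary_polygon=[(float(r), float(c)) for r, c in d["boundary_polygon"]],
            restriction_mode=d.get("restriction_mode", "circle-area"),
            dice=d.get("dice"),
            jaccard_distance=d.get("jaccard_distance"),
            notes=d.get("notes", {}),
        )


def _is_dicom(path: Path) -> bool:
    if path.suffix.lower() in _DICOM_SUFFIXES:
        return True
    try:
        with open(path, "rb") as fh:
            fh.seek(128)
            return fh.read(4) == b"DICM"
    except OSError:
        return False


def read_ct_slice(path, spacing_override: Optional[float] = None) -> CTSlice:
    """Read a CT slice from DICOM, PNG, or TIFF.

    For DICOM, ``spacing_mm`` comes from the PixelSpacing tag unless
    ``spacing_override`` is given; anisotropic row/col spacings are reduced
    to their mean with a warning.  For PNG/TIFF, ``spacing_override`` is
    mandatory.  Intensities are returned exactly as stored.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if spacing_override is not None and not (float(spacing_override) > 0):
        raise ValidationError(f"spacing must be > 0, got {spacing_override!r}")

    if _is_dicom(path):
        ds = pydicom.dcmread(path)
        pixels = ds.pixel_array
        if spacing_override is not None:
            spacing = float(spacing_override)
        else:
            try:
                row_sp, col_sp = (float(v) for v in ds.PixelSpacing)
            except AttributeError as exc:
                raise ConfigurationError(
                    f"{path}: DICOM has no PixelSpacing tag; pass spacing_override"
                ) from exc
            if abs(row_sp - col_sp) > 1e-9:
                warnings.warn(
                    f"anisotropic PixelSpacing ({row_sp}, {col_sp}) mm; using the mean",
                    stacklevel=2,
                )
            spacing = (row_sp + col_sp) / 2.0
        bit_depth = int(getattr(ds, "BitsStored", pixels.dtype.itemsize * 8))
        return CTSlice(pixels, spacing, str(path), bit_depth)

    if spacing_override is None:
        raise ConfigurationError(
            f"{path}: PNG/TIFF input carries no physical spacing; "
            "pass spacing_override in mm/pixel"
        )
    try:
        pixels = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise IOError(f"could not read image {path}: {exc}") from exc
    pixels = np.asarray(pixels)
    if pixels.ndim == 3:
        # accept gray images saved with redundant channels
        if pixels.shape[2] in (3, 4) and np.all(pixels[..., :3] == pixels[..., :1]):
            pixels = pixels[..., 0]
        else:
            raise ValidationError(f"{path}: expected a single-channel grayscale image")
    bit_depth = pixels.dtype.itemsize * 8
    return CTSlice(pixels, float(spacing_override), str(path), bit_depth)


def write_mask(mask: np.ndarray, path, reference_shape: Optional[Sequence[int]] = None) -> Path:
    """Write a binary mask as a lossless 8-bit PNG (0/255).

    ``reference_shape``, when given, must match the mask shape (guards
    against writing a mask for the wrong slice).  Read-back through
    :func:`read_mask` is bit-exact.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValidationError("mask must be 2-D")
    if reference_shape is not None and tuple(mask.shape) != tuple(reference_shape):
        raise ValidationError(
            f"mask shape {mask.shape} does not match slice shape {tuple(reference_shape)}"
        )
    path = Path(path)
    out = np.where(mask.astype(bool), 255, 0).astype(np.uint8)
    iio.imwrite(path, out, extension=path.suffix or ".png")
    return path


def read_mask(path) -> np.ndarray:
    """Read a binary mask image; any nonzero pixel counts as foreground."""
    arr = iio.imread(Path(path))
    arr = np.asarray(arr)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 0


def write_report(report: SegmentationReport, path) -> Path:
    """Serialize a report to pretty-printed JSON at full float precision."""
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
        fh.write("\n")
    return path


def read_report(path) -> SegmentationReport:
    with open(path) as fh:
        return SegmentationReport.from_dict(json.load(fh))
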