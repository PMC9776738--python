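"""Contrast adjustment used by tumor localization.

The localization stage (Otsu binarization + contour filtering) runs on a
contrast-stretched copy of the slice, which sharpens the tissue/air split
and suppresses faint bright spots that would otherwise imitate tumors.
Region growing itself always operates on the ORIGINAL intensities: the
stretch only serves candidate finding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage import exposure

from .errors import ValidationError
from .image_io import CTSlice

__all__ = ["PreprocessParams", "adjust_contrast"]


@dataclass(frozen=True)
class PreprocessParams:
    """Percentile clip points of the linear contrast stretch.

    Intensities at or below the ``low_percentile`` quantile map to 0,
    at or above the ``high_percentile`` quantile to the dtype maximum,
    linearly in between.  Defaults (0.02, 0.98) clip the sparse extreme
    tails (bright specks, reconstruction outliers) without disturbing
    the bulk tissue contrast.
    """

    low_percentile: float = 0.02
    high_percentile: float = 0.98

    def __post_init__(self):
        if not (0.0 <= self.low_percentile < self.high_percentile <= 1.0):
            raise ValidationError(
                "require 0 <= low_percentile < high_percentile <= 1, got "
                f"({self.low_percentile}, {self.high_percentile})"
            )


def _dtype_out_range(dtype: np.dtype) -> tuple[float, float]:
    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        return float(info.min if info.min < 0 else 0), float(info.max)
    return 0.0, 1.0


def adjust_contrast(ct: CTSlice, params: PreprocessParams = PreprocessParams()) -> CTSlice:
    """Linear percentile stretch of a CT slice.

    Returns a new :class:`CTSlice` with the same shape, spacing and dtype.
    A constant image has no stretch to apply; it is returned unchanged with
    a warning.
    """
    px = ct.pixels
    lo, hi = np.percentile(px, (params.low_percentile * 100.0, params.high_percentile * 100.0))
    if not hi > lo:
        warnings.warn(
            "constant or zero-dynamic-range image: contrast left unchanged", stacklevel=2
        )
        return CTSlice(px.copy(), ct.spacing_mm, ct.source_path, ct.bit_depth)
    out_range = _dtype_out_range(px.dtype)
    stretched = exposure.rescale_intensity(
        px.astype(np.float64), in_range=(float(lo), float(hi)), out_range=out_range
    )
    if np.issubdtype(px.dtype, np.integer):
        stretched = np.rint(stretched)
    stretched = stretched.astype(px.dtype)
    return CTSlice(stretched, ct.spacing_mm, ct.source_path, ct.bit_depth)
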