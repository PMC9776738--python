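"""Overlap metrics for segmentation evaluation.

Dice coefficient  D(x, y) = 2|x & y| / (|x| + |y|)
Jaccard distance  dJ(x, y) = 1 - J(x, y) = (|x | y| - |x & y|) / |x | y|

where x is the expert/label pixel set and y the method's pixel set.  Both
are symmetric, bounded in [0, 1], and related by D = 2J / (1 + J).  The
empty-vs-empty comparison is rejected as undefined rather than scored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UndefinedMetricError, ValidationError

__all__ = ["EvalPair", "dice", "jaccard_distance"]


def _as_binary_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x).astype(bool)
    y = np.asarray(y).astype(bool)
    if x.shape != y.shape:
        raise ValidationError(f"mask shapes differ: {x.shape} vs {y.shape}")
    return x, y


def dice(x, y) -> float:
    """Dice coefficient of two binary masks (label first, prediction second)."""
    x, y = _as_binary_pair(x, y)
    nx, ny = int(x.sum()), int(y.sum())
    if nx + ny == 0:
        raise UndefinedMetricError("Dice is undefined for two empty masks")
    inter = int(np.count_nonzero(x & y))
    return 2.0 * inter / (nx + ny)


def jaccard_distance(x, y) -> float:
    """Jaccard distance (1 - intersection over union) of two binary masks."""
    x, y = _as_binary_pair(x, y)
    union = int(np.count_nonzero(x | y))
    if union == 0:
        raise UndefinedMetricError("Jaccard distance is undefined for two empty masks")
    inter = int(np.count_nonzero(x & y))
    return (union - inter) / union


@dataclass
class EvalPair:
    """A (label, prediction) mask pair with metric conveniences."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.x, self.y = _as_binary_pair(self.x, self.y)

    def dice(self) -> float:
        return dice(self.x, self.y)

    def jaccard_distance(self) -> float:
        return jaccard_distance(self.x, self.y)
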