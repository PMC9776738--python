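"""Exception hierarchy for priorgrow."""


class PriorgrowError(Exception):
    """Base class for all priorgrow-specific errors."""


class ConfigurationError(PriorgrowError):
    """Missing or inconsistent configuration (e.g. PNG input without pixel spacing)."""


class ValidationError(PriorgrowError, ValueError):
    """Input violates a documented precondition."""


class DegenerateImageError(ValidationError):
    """Image has no usable dynamic range (constant intensities)."""


class LocalizationError(PriorgrowError):
    """No contour satisfied the prior size/area conditions.

    The tumor could not be localized automatically; the caller may fall back
    to a manually supplied seed point.
    """


class AllRegionsAbnormalError(PriorgrowError):
    """Every grown region failed its growth-restriction credibility check."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class UndefinedMetricError(ValidationError):
    """Overlap metric is undefined (both masks empty)."""
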