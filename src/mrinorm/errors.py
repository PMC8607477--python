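"""Exception hierarchy for mrinorm.

Every error raised by the package derives from :class:`MrinormError` so callers
can catch the whole family at an application boundary (the CLI maps them to a
user-error exit status).
"""


class MrinormError(Exception):
    """Base class for all mrinorm errors."""


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

class MultipleSeriesError(MrinormError):
    """A patient directory contains more than one DICOM series."""


class EmptySeriesError(MrinormError):
    """No readable image slices were found."""


class NonUniformSpacingError(MrinormError):
    """Adjacent slice positions are not uniformly spaced."""


class MissingSliceError(MrinormError):
    """A contour plane matches no image slice within tolerance."""


class UnknownROIError(MrinormError):
    """A structure name cannot be mapped into the controlled ROI vocabulary."""


class UnsupportedFormatError(MrinormError):
    """Requested output format is not supported."""


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

class DegenerateVolumeError(MrinormError):
    """The volume is constant; no foreground/background contrast exists."""


class ZeroRangeError(MrinormError):
    """An intensity range used as a denominator is zero."""


class ZeroVarianceError(MrinormError):
    """The statistics region has zero intensity variance."""


class EmptyMaskError(MrinormError):
    """A mask selects no voxels."""


class MissingROIError(MrinormError):
    """A required ROI mask is absent or empty."""


class NonPositiveReferenceError(MrinormError):
    """The reference-tissue mean intensity is not strictly positive."""


class DegenerateHistogramError(MrinormError):
    """Landmark percentiles collapse (p1 == p99) so no histogram map exists."""


# ---------------------------------------------------------------------------
# Consistency / statistics
# ---------------------------------------------------------------------------

class InsufficientCohortError(MrinormError):
    """Fewer patients than the operation requires."""


class SampleSizeError(MrinormError):
    """Sample size outside the valid range for a statistical test."""


class DegenerateSampleError(MrinormError):
    """All sample values are identical."""


class IncompleteBlockError(MrinormError):
    """A block (ROI) is missing one or more treatment (method) values."""


class AllZeroDifferencesError(MrinormError):
    """Every paired difference is zero; the signed-rank test is undefined."""


# ---------------------------------------------------------------------------
# Synthetic cohorts / configuration
# ---------------------------------------------------------------------------

class SpecValidationError(MrinormError):
    """A phantom-cohort specification violates its invariants."""


class UnknownPresetError(MrinormError):
    """Requested phantom preset name is not registered."""


class ConfigError(MrinormError):
    """A run configuration is invalid."""
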