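"""Domain exceptions raised by the analysis pipeline.

Each exception names the pipeline stage it belongs to, so a failed run can be
reported with a stage tag without string-parsing tracebacks.
"""


class PolaroiError(Exception):
    """Base class for all pipeline errors."""

    stage = "pipeline"


class FormatError(PolaroiError):
    """Input file is not a usable TIFF stack (zero pages, mixed shapes, ...)."""

    stage = "io"


class EmptyImageError(PolaroiError):
    """Frame contains no nonzero pixels after the zero-exclusion rule."""

    stage = "cleaner"


class DegenerateHistogramError(PolaroiError):
    """Too few histogram bins right of the mode for elbow detection."""

    stage = "cleaner"


class EmptyMaskError(PolaroiError):
    """Cleaning removed every foreground pixel."""

    stage = "cleaner"


class AxisUndefinedError(PolaroiError):
    """Foreground spans a single column; no regression line exists."""

    stage = "orient"


class ProcessNotFoundError(PolaroiError):
    """Column profile lacks the two local maxima (soma + process)."""

    stage = "orient"


class LayoutError(PolaroiError):
    """ROI placement failed (no space for ROIs, no clean background, ...)."""

    stage = "roimaker"
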