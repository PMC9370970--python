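"""Exception hierarchy.

Every failure mode of the pipeline maps to a distinct exception type so that
callers (and the CLI) can report which stage failed and why.
"""


class TuberShapeError(Exception):
    """Base class for all package errors."""


class DegenerateSizeError(TuberShapeError):
    """Requested resize would produce an image smaller than 8 px on a side."""


class NoContrastError(TuberShapeError):
    """Image has a single intensity; Otsu thresholding is undefined."""


class EmptyMaskError(TuberShapeError):
    """A mask has no foreground pixels where at least one is required."""


class ObjectTooLargeError(TuberShapeError):
    """Foreground cannot be centred (or traced) without leaving the canvas."""


class ContourError(TuberShapeError):
    """Contour extraction or polygon measurement failed."""


class EllipseFitError(TuberShapeError):
    """Least-squares conic fit did not produce a valid ellipse."""


class NotAnEllipseError(EllipseFitError):
    """Conic coefficients describe a parabola/hyperbola, not an ellipse."""


class ExtentMismatchError(TuberShapeError):
    """Two masks with different extents were combined."""


class SpecError(TuberShapeError):
    """Invalid synthetic shape specification."""


class StageError(TuberShapeError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
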