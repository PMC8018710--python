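"""Exception hierarchy shared across the package."""


class HistopamError(Exception):
    """Base class for package errors."""


class InvalidGeometryError(HistopamError, ValueError):
    """Source/aperture/grid geometry is inconsistent or degenerate."""


class WidthsUnresolvedError(HistopamError, ValueError):
    """The half-peak contour is clipped by the grid boundary."""


class TruncationError(HistopamError, ValueError):
    """A required delay or arrival falls outside the recorded window."""


class GridMismatchError(HistopamError, ValueError):
    """Two gridded objects do not share the same grid/geometry."""


class UndefinedCentroidError(HistopamError, ValueError):
    """Centroid requested of an all-zero map or empty mask."""


class DegenerateHistogramError(HistopamError, ValueError):
    """Otsu thresholding requested of a (near-)constant image."""


class NumericFailureError(HistopamError, RuntimeError):
    """A numerical solve (e.g. the Lagrange-multiplier root) failed."""
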