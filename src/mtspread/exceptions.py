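"""Exception hierarchy for mtspread.

Every error raised on a user-facing code path derives from
:class:`MtspreadError` so callers can catch the package's failures
without swallowing programming errors.
"""


class MtspreadError(Exception):
    """Base class for all mtspread errors."""


class ValidationError(MtspreadError):
    """A table, matrix, or config violates its documented contract."""


class SizingError(MtspreadError):
    """A requested synthesis cannot fit (e.g. too many ROIs for the grid)."""


class DegenerateGraphError(MtspreadError):
    """The structural graph has no edges at the requested density."""


class SampleSizeError(MtspreadError):
    """Too few subjects (or edges, or permutations) for the operation."""


class TracerMismatchError(MtspreadError):
    """A tracer was passed to a classifier that does not handle it."""


class IncompleteMetaRoiError(MtspreadError):
    """The temporal meta-ROI composite is missing one of its six regions."""


class MissingFitError(MtspreadError):
    """An ROI to be scored has no fitted mixture parameters."""


class InvalidFitError(MtspreadError):
    """Mixture parameters are unusable (e.g. non-positive sigma)."""


class GridError(MtspreadError):
    """Volumes passed to an image-space operation have mismatched shapes."""


class GeometryError(MtspreadError):
    """A streamline is degenerate (zero length / fewer than two points)."""


class UndefinedCorrelationError(MtspreadError):
    """A correlation is undefined because an input is constant."""


class CollinearityError(MtspreadError):
    """The regression design is (numerically) rank deficient."""


class KindMismatchError(MtspreadError):
    """Tables of different value kinds (scores vs SUVRs) were mixed."""


class SemanticsError(MtspreadError):
    """Edge matrices with incompatible semantics were combined."""
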