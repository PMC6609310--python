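"""Exception hierarchy for decm.

All package-specific failures derive from :class:`DecmError` so callers can
catch one type at pipeline level while tests discriminate on subclasses.
"""


class DecmError(Exception):
    """Base class for all decm errors."""


class FormatError(DecmError):
    """A file parsed but does not have the expected structure (e.g. a 5-D image)."""


class ValidationError(DecmError):
    """An input value violates a documented precondition."""


class ShapeError(DecmError):
    """Array/grid shapes or affines that must agree do not."""


class WindowTooShortError(ValidationError):
    """A correlation window with fewer than 3 time points was requested."""


class DegenerateDesignError(ValidationError):
    """A regression design matrix is rank deficient (collinear columns)."""


class InsufficientDofError(ValidationError):
    """Not enough time points / subjects for the requested model."""
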