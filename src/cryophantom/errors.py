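"""Exception types shared across the package."""


class CryoPhantomError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(CryoPhantomError, ValueError):
    """A parameter violates a documented precondition."""


class FormatError(CryoPhantomError, ValueError):
    """A file (MRC header, ground-truth sidecar, metric table) is malformed.

    The message names the offending field.
    """


class DegenerateInputError(CryoPhantomError, ValueError):
    """Input carries no usable information (zero variance, flat surface)."""


class AlignmentFailureError(CryoPhantomError, RuntimeError):
    """Too many pairwise shift measurements exceeded the expected-shift bound."""


class UndefinedCVError(CryoPhantomError, ZeroDivisionError):
    """Coefficient of variation undefined: mean is zero after trimming."""
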