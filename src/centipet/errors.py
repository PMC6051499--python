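"""Exception hierarchy shared across the package."""


class CentipetError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(CentipetError, ValueError):
    """A parameter object failed validation; the message names the field."""


class AnchorOrderError(ParameterError):
    """Anchor means out of order (AD anchor must exceed YC anchor)."""


class EmptyWindowError(CentipetError, ValueError):
    """No time frames fall inside the requested window."""


class InsufficientDataError(CentipetError, ValueError):
    """Too few observations for the requested computation."""


class NumericalDomainError(CentipetError, ValueError):
    """A value left the mathematical domain of an operation (e.g. divide by
    a non-positive reference mean, non-positive tail activity)."""


class ConditioningError(CentipetError, ValueError):
    """Mixing matrix is singular or too ill-conditioned to invert."""


class RegionLookupError(CentipetError, KeyError):
    """Requested region names absent from a regional value set."""


class DegenerateFitError(CentipetError, ValueError):
    """Regression input is degenerate (constant predictor, zero variance)."""


class SchemaError(CentipetError, ValueError):
    """A delimited input file is missing required columns or has malformed
    cells; the message carries the column name or line number."""
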