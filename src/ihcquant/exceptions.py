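"""Exception hierarchy used across the pipeline.

All errors raised by ihcquant derive from :class:`IHCQuantError` so callers
can catch pipeline failures without masking programming errors.
"""


class IHCQuantError(Exception):
    """Base class for all ihcquant errors."""


class FormatError(IHCQuantError):
    """Input has the wrong dtype, shape, or file format."""


class ParameterError(IHCQuantError):
    """A configuration parameter is outside its valid range."""


class DegeneracyError(IHCQuantError):
    """A matrix or geometric construction is degenerate (singular, collinear)."""


class IntegrityError(IHCQuantError):
    """Internal consistency violated (empty nucleus, mismatched core lists)."""


class ValidationError(IHCQuantError):
    """A data value or table violates its declared schema or domain."""


class InsufficientDataError(IHCQuantError):
    """Too few observations to run the requested analysis."""


class FeasibilityError(IHCQuantError):
    """A randomized construction could not be satisfied within its retry bound."""
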