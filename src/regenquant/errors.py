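"""Exception hierarchy shared across the package.

All errors derive from :class:`RegenQuantError` (itself a ``ValueError``)
so callers can catch package failures with a single except clause while
plain ``ValueError`` semantics are preserved for library users.
"""


class RegenQuantError(ValueError):
    """Base class for all package errors."""


class ConfigurationError(RegenQuantError):
    """A simulation or analysis configuration is invalid."""


class InputError(RegenQuantError):
    """An input array, file, or annotation does not satisfy preconditions."""


class MeasurementError(RegenQuantError):
    """A measurement could not be taken (e.g. empty mask at a position)."""


class SegmentationError(RegenQuantError):
    """Automatic segmentation found no usable object."""


class AnalysisError(RegenQuantError):
    """A downstream computation received degenerate data."""
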