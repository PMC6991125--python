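"""Exception hierarchy.

Every error raised by bloomfit derives from :class:`BloomfitError` so callers
(and the CLI) can catch the package's failures in one place.
"""


class BloomfitError(Exception):
    """Base class for all bloomfit errors."""


class InvalidParameterError(BloomfitError, ValueError):
    """Model parameters are non-finite or non-positive."""


class InvalidCountError(BloomfitError, ValueError):
    """A cell count is non-positive (the ln transform is undefined)."""


class InsufficientDataError(BloomfitError, ValueError):
    """A time series is too short for the requested operation."""


class InsufficientReplicationError(BloomfitError, ValueError):
    """A design cell has fewer replicates than the model requires."""


class ConsistencyError(BloomfitError, ValueError):
    """Paired objects (series / fit) disagree on identifying metadata."""


class SpecificationError(BloomfitError, ValueError):
    """A requested cell, margin, level or response does not exist."""


class ConfigurationError(BloomfitError, ValueError):
    """An option value is outside its documented domain."""


class UndefinedImpactError(BloomfitError, ZeroDivisionError):
    """Percent impact is undefined because the two condition means average to zero."""


class SchemaError(BloomfitError, ValueError):
    """An input table violates the documented column schema."""


class EmptyInputError(BloomfitError, ValueError):
    """A writer was handed an empty record collection."""
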