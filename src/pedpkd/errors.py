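"""Exception hierarchy used across the package."""


class PedpkdError(Exception):
    """Base class for all package errors."""


class InvalidInputError(PedpkdError, ValueError):
    """A value violates a documented precondition (negative area, zero height, ...)."""


class ConfigurationError(PedpkdError):
    """A required configuration item (e.g. an eGFR coefficient row) is missing."""


class OutOfRangeError(PedpkdError):
    """An anchor value falls outside a normative table; no extrapolation is done."""


class IncompleteProfileError(PedpkdError):
    """An ambulatory BP profile is missing one of the four period x component values."""


class EmptySeriesError(PedpkdError):
    """A segmentation mask contains no voxels with the requested label."""


class SchemaError(PedpkdError):
    """A CSV file does not match its documented schema."""


class GenerationError(PedpkdError):
    """The synthetic generator cannot satisfy its constraints (infeasible band etc.)."""
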