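"""Exception hierarchy shared across the pipeline."""


class SorgwueError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SorgwueError):
    """A file could not be parsed as the expected format."""


class SchemaError(SorgwueError):
    """A table is missing a mandatory column or has the wrong shape."""


class ValidationError(SorgwueError):
    """An in-memory object violates one of its invariants."""


class ConfigError(SorgwueError):
    """A configuration value is out of its admissible range."""


class InputError(SorgwueError):
    """A function argument violates a precondition."""


class FitError(SorgwueError):
    """A model fit cannot be performed on the given data."""


class AggregationError(SorgwueError):
    """Surface- or group-level aggregation received incomplete input."""
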