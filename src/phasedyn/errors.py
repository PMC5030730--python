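"""Exception hierarchy shared across the package."""


class PhasedynError(Exception):
    """Base class for all package-specific errors."""


class InputError(PhasedynError):
    """Malformed input data (wrong dimensionality, shape mismatch, ...)."""


class ParameterError(PhasedynError):
    """A parameter value outside its documented domain."""


class ParseError(PhasedynError):
    """A filename or table that does not match its declared layout."""


class SchemaError(PhasedynError):
    """A table missing required columns."""


class ValidationError(PhasedynError):
    """A table violating a uniqueness or consistency constraint."""


class FormatError(PhasedynError):
    """A persisted file whose contents cannot be interpreted."""


class JoinError(PhasedynError):
    """A strict metadata join that would drop or orphan rows."""


class GenerationError(PhasedynError):
    """Synthetic data could not be generated under the given constraints."""


class InsufficientDataError(PhasedynError):
    """Not enough observations for a requested fit or statistic."""
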