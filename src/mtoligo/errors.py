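"""Exception hierarchy shared across the package."""


class MtOligoError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MtOligoError):
    """A file does not conform to the expected dialect (e.g. missing column)."""


class ParseError(MtOligoError):
    """A cell or line could not be interpreted; carries the offending row."""


class ConfigurationError(MtOligoError):
    """Invalid or contradictory parameter values."""


class ValidationError(MtOligoError):
    """Input data violate a documented precondition."""


class DegeneratePathError(MtOligoError):
    """A filament trace is too short or collapsed to define a path."""
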