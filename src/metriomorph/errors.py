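"""Exception hierarchy shared across the toolkit."""


class MetriomorphError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MetriomorphError):
    """Input fails a structural precondition (missing landmark, bad label...)."""


class ParseError(MetriomorphError):
    """A file could not be parsed; message carries location where possible."""


class FormatError(MetriomorphError):
    """A file parsed but violates the declared format (dimension mismatch...)."""


class GeometryError(MetriomorphError):
    """Landmark configuration is geometrically degenerate or infeasible."""


class DomainError(MetriomorphError):
    """Numeric argument outside its mathematical domain."""
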