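"""Exception hierarchy shared across pipeline stages."""


class PalmitomeError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PalmitomeError, ValueError):
    """A configuration object or parameter combination is invalid."""


class FormatError(PalmitomeError, ValueError):
    """An input file does not conform to its declared schema."""


class IntegrityError(PalmitomeError, ValueError):
    """A structural invariant of a loaded dataset is violated."""


class ValidationError(PalmitomeError, ValueError):
    """Arguments violate an operation's preconditions."""


class AmbiguousNamespaceError(PalmitomeError, ValueError):
    """Identifier namespace detection could not pick a majority winner."""

    def __init__(self, message: str, candidates=None):
        super().__init__(message)
        self.candidates = candidates or []


class ParseError(PalmitomeError, ValueError):
    """A token (e.g. a substitution like ``C6F``) could not be parsed."""
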