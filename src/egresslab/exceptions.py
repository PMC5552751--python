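"""Exception types shared across the package."""


class EgressLabError(Exception):
    """Base class for all package errors."""


class ParameterError(EgressLabError, ValueError):
    """A physical or geometric parameter is out of its documented range."""


class ConfigurationError(EgressLabError, ValueError):
    """A run configuration or system definition is inconsistent."""


class AlignmentError(EgressLabError, ValueError):
    """Rigid superposition is not defined for the given point sets."""


class IntegrationError(EgressLabError, RuntimeError):
    """The dynamics produced non-finite forces or coordinates."""


class ParseError(EgressLabError, ValueError):
    """A file could not be parsed; carries the offending location."""
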