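"""Exception hierarchy.

All package errors derive from :class:`PerilesionError` so callers can catch
one type at pipeline boundaries while tests can assert on the precise class.
"""


class PerilesionError(Exception):
    """Base class for all errors raised by perilesion."""


class FormatError(PerilesionError):
    """Input file does not match the expected on-disk format."""


class ValidationError(PerilesionError):
    """Data violates an invariant (negative intensity, unknown label, ...)."""


class ParameterError(PerilesionError):
    """A numeric parameter is outside its valid domain."""


class ConfigurationError(PerilesionError):
    """A rule set or run configuration is inconsistent."""


class StateError(PerilesionError):
    """An operation was applied to a table in the wrong transform state."""
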