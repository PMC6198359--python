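"""Exception hierarchy for spermclock.

All errors raised by this package derive from :class:`SpermclockError` so
callers (and the CLI) can distinguish package errors from programming bugs.
"""


class SpermclockError(Exception):
    """Base class for all spermclock errors."""


class FormatError(SpermclockError):
    """A file could not be parsed (malformed header, garbled content)."""


class ValidationError(SpermclockError):
    """Parsed content violates a domain invariant (range, uniqueness, shape)."""


class ConfigurationError(SpermclockError):
    """Inputs are individually valid but mutually inconsistent.

    Example: probe manifest uses ``chr11`` style chromosome names while the
    region table uses bare ``11``.
    """


class InputError(SpermclockError):
    """An operation was called with unusable inputs (too few samples, empty group)."""


class VersionError(SpermclockError):
    """A serialized artifact has an unsupported schema version."""
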