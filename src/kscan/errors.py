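"""Exception hierarchy.

``UsageError`` maps to CLI exit code 1, ``DataError`` (and subclasses)
to exit code 2; anything else is a bug.
"""


class KscanError(Exception):
    """Base class for all package errors."""


class UsageError(KscanError):
    """Bad invocation: missing files, inconsistent flags."""

    exit_code = 1


class DataError(KscanError):
    """Invalid or inconsistent input data."""

    exit_code = 2


class ValidationError(DataError):
    """A structural invariant of a database or alignment is violated."""


class EngineError(KscanError):
    """An external search engine failed or is unavailable."""
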