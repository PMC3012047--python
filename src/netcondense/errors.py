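"""Exception hierarchy.

Every error raised by the library derives from :class:`NetcondenseError`,
so callers (and the CLI) can distinguish domain failures from bugs.
"""


class NetcondenseError(Exception):
    """Base class for all library errors."""


class FormatError(NetcondenseError):
    """A file could not be parsed under the named dialect."""


class TypingError(NetcondenseError):
    """An edge carries an interaction-type value with no mapping."""


class SchemaError(NetcondenseError):
    """A required column or key is missing from tabular input."""


class ParseError(NetcondenseError):
    """A cell or token could not be converted to the expected type."""


class IntegrityError(NetcondenseError):
    """Input violates a uniqueness or referential-integrity contract."""


class CoverageError(NetcondenseError):
    """Network nodes lack measurements under an `error` missing-data policy."""


class DegenerateVarianceError(NetcondenseError):
    """Pooled replicate variance is zero; the Welch differential is undefined."""


class StateError(NetcondenseError):
    """An operation was invoked on input it cannot act on (e.g. empty scores)."""


class ConfigError(NetcondenseError):
    """A run configuration failed validation; message lists all violations."""
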