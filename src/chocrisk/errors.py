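"""Exception hierarchy.

All chocrisk errors derive from :class:`ChocriskError` so callers can catch
the package's failures with one clause; each subclass also derives from
``ValueError`` to stay friendly to generic error handling.
"""


class ChocriskError(ValueError):
    """Base class for all chocrisk errors."""


class SchemaError(ChocriskError):
    """An input table is missing required columns or is otherwise malformed."""


class ValidationError(ChocriskError):
    """One or more records violate domain invariants; message names the rows."""


class DomainError(ChocriskError):
    """A scalar argument is outside its mathematical/physical domain."""


class SpecError(ChocriskError):
    """A distribution or Monte Carlo model specification is invalid/incomplete."""


class InfeasibleSpecError(SpecError):
    """A summary-statistic spec cannot be realised (e.g. rejection rate too low)."""
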