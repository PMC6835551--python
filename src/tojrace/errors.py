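"""Exception hierarchy for tojrace.

All package errors derive from :class:`TojraceError` so callers can catch
everything with one clause; the subclasses distinguish bad model parameters,
bad numerical inputs, malformed data files, and fitting failures.
"""


class TojraceError(Exception):
    """Base class for all tojrace errors."""


class InvalidParameterError(TojraceError, ValueError):
    """A model parameter violates its constraints (e.g. a non-positive rate)."""


class InvalidInputError(TojraceError, ValueError):
    """A numerical input is out of domain (e.g. a non-finite SOA)."""


class ConfigurationError(TojraceError, ValueError):
    """A design or run configuration is malformed."""


class SchemaError(TojraceError, ValueError):
    """A data file does not conform to the judgment-CSV schema."""


class DegenerateDataError(TojraceError, ValueError):
    """Judgment data carries no information about the curve location
    (every count is 0 or every count equals the trial number)."""


class FitFailureError(TojraceError, RuntimeError):
    """Every optimization start failed; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class InconsistentComparisonError(TojraceError, ValueError):
    """Model fits being compared were not obtained on the same data."""
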