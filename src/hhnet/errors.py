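"""Exception types shared across the pipeline."""


class HHNetError(Exception):
    """Base class for package errors."""


class SchemaError(HHNetError):
    """An input file does not match the documented schema."""


class RosterValidationError(HHNetError):
    """One or more rows violate roster invariants.

    Carries the row-level diagnostics so callers can report every
    offending record, not only the first.
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = list(diagnostics or [])


class OrphanRecordError(HHNetError):
    """A child record references a household absent from the roster."""


class DegenerateNetworkError(HHNetError):
    """The ego has no alters; structural measures are undefined."""


class ConvergenceError(HHNetError):
    """A model fit failed to converge (e.g. separation)."""


class ConfigError(HHNetError):
    """A configuration object violates its invariants."""
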