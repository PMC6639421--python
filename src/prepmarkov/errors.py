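"""Exception hierarchy shared across the package."""


class PrepMarkovError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PrepMarkovError):
    """A config file, column mapping or model spec is invalid."""


class DataError(PrepMarkovError):
    """Input data violate a structural precondition (coverage, alignment, coding)."""


class EventLogParseError(DataError):
    """One or more event-log rows could not be parsed.

    Carries the offending line numbers so callers can report them instead of
    silently dropping rows.
    """

    def __init__(self, message: str, bad_lines=None):
        super().__init__(message)
        self.bad_lines = list(bad_lines or [])


class FitError(PrepMarkovError):
    """The likelihood machinery was asked for something it cannot provide."""
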