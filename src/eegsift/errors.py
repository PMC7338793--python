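"""Exception hierarchy shared across the package."""


class EEGSiftError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(EEGSiftError, ValueError):
    """An argument violates a documented precondition."""


class ParseError(EEGSiftError, ValueError):
    """A Bonn-format text file could not be parsed."""

    def __init__(self, message: str, path=None, line: int | None = None):
        super().__init__(message)
        self.path = path
        self.line = line


class EmptyDatasetError(EEGSiftError, ValueError):
    """A dataset scan matched no files."""


class MonotoneRemainder(EEGSiftError):
    """Raised by envelope fitting when too few extrema remain.

    Signals to the sifting loop that the running remainder is a monotone
    trend and decomposition of this branch is complete.
    """


class NoInformativeIMFs(EEGSiftError, ValueError):
    """Every IMF fell below the correlation threshold."""


class InsufficientMatches(EEGSiftError, ValueError):
    """Sample entropy found no matching template pairs at length m."""


class FeatureDomainError(EEGSiftError, ValueError):
    """A feature is undefined on this record (e.g. zero-mean variation coefficient)."""

    def __init__(self, message: str, feature: str | None = None, record_id: str | None = None):
        super().__init__(message)
        self.feature = feature
        self.record_id = record_id


class OptimizerError(EEGSiftError, RuntimeError):
    """The grey wolf optimizer hit a non-finite objective value."""
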