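"""Exception hierarchy for the QA pipeline.

Every failure mode that QA must surface (rather than guess through) gets its
own class so callers can distinguish configuration mistakes from bad input
data from genuine measurement failures.
"""


class DynQAError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DynQAError):
    """Invalid plan or simulation configuration."""


class ValidationError(DynQAError):
    """A domain object violates one of its invariants."""


class ParseError(DynQAError):
    """A document or log stream could not be parsed.

    ``location`` is a human-readable hint (line number, element name).
    """

    def __init__(self, message: str, location: str | None = None):
        self.location = location
        if location is not None:
            message = f"{message} (at {location})"
        super().__init__(message)


class SynchronizationError(DynQAError):
    """Log streams could not be temporally aligned."""


class DetectionFailedError(DynQAError):
    """No ball-bearing candidate found in an MV image.

    QA must flag a failed detection explicitly; silently reporting a guessed
    center would defeat the purpose of the test.
    """


class UnsupportedGeometryError(DynQAError):
    """Image acquired at a gantry angle the analysis does not support."""


class ConsistencyError(DynQAError):
    """Measurements could not be matched one-to-one onto plan steps."""
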