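"""Exception hierarchy for snfdid."""


class SnfDidError(Exception):
    """Base class for all package errors."""


class ConfigError(SnfDidError):
    """Invalid simulation or model configuration; message names the field."""


class InvalidCodeError(SnfDidError):
    """A diagnosis code string is not syntactically valid ICD-10."""


class DataIntegrityError(SnfDidError):
    """Duplicate identifiers or dangling references between tables."""


class GenerationError(SnfDidError):
    """The synthetic generator cannot proceed (e.g. no facilities of a setting)."""


class CalibrationError(SnfDidError):
    """Generator calibration failed to converge.

    Carries the iteration ``trace`` and the ``best_config`` iterate (the
    configuration whose measured moments came closest to the targets), so
    callers that can tolerate a near-miss may proceed deliberately.
    """

    def __init__(self, message, trace=None, best_config=None):
        super().__init__(message)
        self.trace = trace or []
        self.best_config = best_config


class SpecificationError(SnfDidError):
    """A model specification cannot be estimated on the given panel."""


class SingularityError(SnfDidError):
    """Design matrix is rank deficient after the within-transformation."""

    def __init__(self, message, columns=None):
        super().__init__(message)
        self.columns = list(columns or [])


class DomainError(SnfDidError):
    """An argument is outside the mathematical domain of an operation."""
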