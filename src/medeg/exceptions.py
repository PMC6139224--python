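"""Exception hierarchy for the medeg package."""


class MedegError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MedegError, ValueError):
    """An input violates a documented precondition."""


class ConfigurationError(MedegError, ValueError):
    """A simulation or model configuration is internally inconsistent."""


class EstimationError(MedegError, RuntimeError):
    """A model cannot be estimated (e.g. singular design matrix)."""


class UndefinedCorrelationError(MedegError, ValueError):
    """Correlation is undefined because one input has zero variance."""
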