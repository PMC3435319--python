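"""Exception hierarchy for saltcvd."""


class SaltCVDError(Exception):
    """Base class for all saltcvd errors."""


class ConfigurationError(SaltCVDError, ValueError):
    """Invalid generator, scenario or run configuration."""


class DomainError(SaltCVDError, ValueError):
    """An argument outside its scientific domain (negative rate, prevalence > 1, ...)."""


class FormatError(SaltCVDError, ValueError):
    """A serialized input table is malformed or incomplete."""


class CalibrationError(SaltCVDError, RuntimeError):
    """Iterative calibration failed to converge; carries residuals."""

    def __init__(self, message: str, residuals: dict | None = None):
        super().__init__(message)
        self.residuals = residuals or {}


class EngineError(SaltCVDError, RuntimeError):
    """Internal inconsistency during a simulation step (e.g. negative count)."""
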