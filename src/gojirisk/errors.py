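"""Exception hierarchy shared across the pipeline stages."""


class GojiRiskError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(GojiRiskError):
    """A file does not conform to the expected column schema."""


class ValidationError(GojiRiskError):
    """A parsed value violates a domain invariant."""


class DomainError(GojiRiskError, ValueError):
    """A numeric argument lies outside the mathematical domain of an operation."""


class EmptyDataError(GojiRiskError):
    """An operation received no records to work on."""


class InsufficientDataError(GojiRiskError):
    """Too few observations to fit a parametric family."""


class DegenerateDataError(GojiRiskError):
    """Zero-variance data cannot identify a continuous family."""


class FitError(GojiRiskError):
    """A single distribution fit failed (support violation, non-convergence)."""


class NoFitError(FitError):
    """Every candidate family failed; carries per-family diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ConfigurationError(GojiRiskError):
    """A run configuration is incomplete or inconsistent."""


class SensitivityError(GojiRiskError):
    """Sensitivity shares are undefined (e.g., all inputs constant)."""
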