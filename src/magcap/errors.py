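"""Exception hierarchy for magcap.

All package-specific failures derive from :class:`MagcapError` so callers can
catch everything from one base, while the physics/validation errors also
derive from ``ValueError`` for idiomatic use.
"""


class MagcapError(Exception):
    """Base class for all magcap errors."""


class DomainError(MagcapError, ValueError):
    """An argument lies outside the physical domain of the model."""


class ModelValidityError(MagcapError, ValueError):
    """Inputs violate the validity region of a sub-model (e.g. mixing rule)."""


class InsufficientDataError(MagcapError, ValueError):
    """Too few data points to perform a fit."""


class FitFailureError(MagcapError, RuntimeError):
    """A least-squares fit failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class StepSizeError(MagcapError, ValueError):
    """Integration step too coarse for the field's length scale."""


class InfeasibleTargetError(MagcapError, ValueError):
    """A calibration target cannot be reached within the parameter bound."""


class CalibrationError(MagcapError, RuntimeError):
    """Susceptibility calibration failed; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ConfigError(MagcapError, ValueError):
    """Configuration file failed validation; message lists all violations."""
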