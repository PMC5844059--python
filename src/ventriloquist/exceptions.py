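"""Exception types shared across the package."""


class VentriloquistError(Exception):
    """Base class for all package-specific errors."""


class InvalidDesignError(VentriloquistError):
    """Raised when an experimental design request is inconsistent."""


class ReproducibilityError(VentriloquistError):
    """Raised when a stochastic operation is invoked without a seeded RNG."""


class InvalidResponseError(VentriloquistError):
    """Raised when a response value is not a location on the button grid."""


class EmptySummaryError(VentriloquistError):
    """Raised when a binomial summary is requested from an empty trial table."""


class FitFailureError(VentriloquistError):
    """Raised when no optimizer restart converged; carries the best candidate."""

    def __init__(self, message, best_result=None):
        super().__init__(message)
        self.best_result = best_result


class NormalizationError(VentriloquistError):
    """Raised when a z-normalization group has zero variance."""


class DecodingError(VentriloquistError):
    """Raised when classifier training is impossible (e.g., a single class)."""


class IncompleteSummaryError(VentriloquistError):
    """Raised when decoded labels do not cover every requested condition."""


class DegenerateContrastError(VentriloquistError):
    """Raised when an ANOVA contrast has zero variance across subjects."""


class UndefinedTestError(VentriloquistError):
    """Raised when a signed-rank test has no nonzero differences."""
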