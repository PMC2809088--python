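"""Exception hierarchy shared across the package."""


class TilepathError(Exception):
    """Base class for all package errors."""


class FormatError(TilepathError):
    """A file does not conform to its declared format."""


class DataError(TilepathError):
    """Input data violate a contract (duplicates, missing values, unknown names)."""


class ValidationError(TilepathError):
    """An in-memory object violates its invariants."""


class ConfigurationError(TilepathError):
    """Run parameters are inconsistent or incomplete."""


class CalibrationError(TilepathError):
    """Threshold calibration could not reach the FDR target.

    Carries ``best_ratio``, the smallest randomized/real peak-count ratio
    observed over the grid (None if no threshold produced real peaks).
    """

    def __init__(self, message: str, best_ratio=None, trace=None):
        super().__init__(message)
        self.best_ratio = best_ratio
        self.trace = trace


class BudgetError(TilepathError):
    """An assembled design exceeds the probe budget.

    Carries ``overshoot`` (probes over budget) and ``breakdown``
    (per-source probe counts).
    """

    def __init__(self, message: str, overshoot: int, breakdown=None):
        super().__init__(message)
        self.overshoot = overshoot
        self.breakdown = breakdown or {}


class SimulationError(TilepathError):
    """A synthetic fixture could not be generated under the given constraints."""
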