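"""Exception hierarchy for soyemerge."""


class SoyemergeError(Exception):
    """Base class for all package-specific errors."""


class DegenerateDataError(SoyemergeError):
    """Raised when input data carry no usable signal (e.g. all-zero counts)."""


class InsufficientDataError(SoyemergeError):
    """Raised when too few observations exist for the requested estimate."""


class FitFailureError(SoyemergeError):
    """Raised when a non-linear fit fails to converge after bounded restarts.

    Carries the best residual sum of squares reached, if any attempt produced
    a finite objective value.
    """

    def __init__(self, message: str, best_rss: float | None = None):
        super().__init__(message)
        self.best_rss = best_rss


class EstimationError(SoyemergeError):
    """Raised when an estimator's assumptions are violated (e.g. no thermal
    response: non-positive slope of germination rate against temperature)."""


class ConfigError(SoyemergeError):
    """Raised for invalid seedbed / simulation configuration."""


class InputError(SoyemergeError):
    """Raised for malformed runtime inputs (length mismatches, negative
    rainfall, missing weather days, observation dates beyond the horizon)."""
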