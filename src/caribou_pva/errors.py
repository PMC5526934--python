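"""Exception hierarchy for the caribou demographic pipeline."""


class CaribouPVAError(Exception):
    """Base class for all package-specific errors."""


class MalformedRecordError(CaribouPVAError):
    """A telemetry or survey record violates its schema (e.g. exit before entry)."""


class FilteredOut(CaribouPVAError):
    """Signal that a record or population-year was excluded by a monitoring filter.

    Not a failure: callers batch-processing data catch this and log the
    reason so every input record is accounted for.
    """

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


class InconsistentDataError(CaribouPVAError):
    """Internally contradictory data (e.g. a death with an empty risk set)."""


class UndefinedRatioError(CaribouPVAError):
    """A ratio is requested from counts that are all zero."""


class MissingCovariateError(CaribouPVAError):
    """A required covariate (e.g. lagged disturbance) is absent from the range table."""


class FitFailureError(CaribouPVAError):
    """Model fitting did not converge; the message carries optimizer diagnostics."""


class RankDeficiencyError(FitFailureError):
    """The (weighted) design matrix is rank deficient."""


class SeparationError(FitFailureError):
    """Complete or quasi-complete separation: the binomial MLE diverges."""


class BootstrapUnstableError(CaribouPVAError):
    """More than the tolerated fraction of bootstrap refits failed."""


class UncertaintyUnavailableError(CaribouPVAError):
    """An operation needs a coefficient covariance matrix the model does not carry."""


class DomainError(CaribouPVAError, ValueError):
    """An argument lies outside the mathematical domain of the operation."""
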