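"""Exception hierarchy for herdfap."""


class HerdFapError(Exception):
    """Base class for all herdfap errors."""


class ConfigError(HerdFapError):
    """Bad configuration, e.g. a mandatory column missing after mapping."""


class DomainError(HerdFapError, ValueError):
    """An input is outside the mathematical domain of an operation."""


class InsufficientDataError(HerdFapError):
    """Too few records/lactations to attempt a fit."""


class ZeroVarianceError(HerdFapError):
    """A regression predictor has no variance."""


class FitError(HerdFapError):
    """A nonlinear fit failed to converge.

    Carries the best attempt found so far in ``best_params``.
    """

    def __init__(self, message, best_params=None):
        super().__init__(message)
        self.best_params = best_params


class ModelIncompleteError(HerdFapError):
    """A prediction was requested from a HerdModel missing a fitted component."""
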