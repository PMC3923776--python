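"""Exception hierarchy shared across the package."""


class SpatregimeError(Exception):
    """Base class for all package errors."""


class InvalidInputError(SpatregimeError, ValueError):
    """Non-finite or out-of-domain values in user data."""


class InvalidConfigError(SpatregimeError, ValueError):
    """A configuration value violates its contract (e.g. radius <= 0)."""


class AmbiguousRegionError(SpatregimeError, ValueError):
    """A point is claimed by more than one region polygon."""


class CoverageError(SpatregimeError, ValueError):
    """A lagged averaging window extends outside the available years."""


class EmptyPeriodError(SpatregimeError, ValueError):
    """A period of a threshold specification contains no observations."""


class SingularFitError(SpatregimeError, ValueError):
    """The design matrix lost the intercept (or all columns) to aliasing."""


class UndefinedAdjustmentError(SpatregimeError, ValueError):
    """Adjusted explained deviance is undefined (n <= p)."""


class ExhaustedCandidatesError(SpatregimeError, ValueError):
    """No admissible candidate year remains at a gain-profile step."""
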