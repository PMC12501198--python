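"""Exception types raised across the package."""


class PhiIDError(Exception):
    """Base class for all package-specific errors."""


class NumericalDegeneracyError(PhiIDError):
    """A required (sub)covariance matrix is singular even after jitter,
    or an estimator received degenerate (e.g. constant-column) data."""


class NonstationarySystemError(PhiIDError):
    """The coupling matrix has spectral radius >= 1, so no stationary
    distribution exists."""


class UnsupportedBackendError(PhiIDError):
    """The requested redundancy backend does not support this system kind."""


class InternalConsistencyError(PhiIDError):
    """A built-in construction failed its own decomposition oracle check."""


class DegenerateConditioningError(PhiIDError):
    """Partial correlation is undefined because the conditioning variable is
    perfectly correlated with one of the arguments."""


class InsufficientDataError(PhiIDError):
    """Too few valid observations/pairs for the requested analysis."""
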