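"""Exception hierarchy shared across the package."""


class MBHVError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MBHVError):
    """Invalid user configuration: missing columns, bad option values."""


class DataError(MBHVError):
    """Invalid input data: missing values, non-numeric cells, too few rows."""


class DegenerateDataError(DataError):
    """Data whose covariance is singular or indefinite.

    The pooled sample covariance must serve as a Wishart prior scale, so it
    has to be strictly positive definite.
    """


class GeometryError(MBHVError):
    """Invalid hypervolume geometry (non-SPD covariance, dimension mismatch)."""


class DiagnosticError(MBHVError):
    """A convergence diagnostic was requested on an unsuitable ensemble."""


class NumericalError(MBHVError):
    """Non-finite values encountered during sampling."""


class ConvergenceWarning(UserWarning):
    """Emitted when the Gelman-Rubin diagnostic exceeds its threshold."""
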