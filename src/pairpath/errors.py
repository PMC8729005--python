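"""Exception hierarchy for pairpath."""


class PairpathError(Exception):
    """Base class for all pairpath errors."""


class ValidationError(PairpathError):
    """Structural validation of an input matrix or table failed."""


class InvalidModelError(PairpathError):
    """A partial-correlation matrix does not define a valid Gaussian model.

    Carries the offending minimum eigenvalue of the normalized precision.
    """

    def __init__(self, message: str, min_eigenvalue: float | None = None):
        super().__init__(message)
        self.min_eigenvalue = min_eigenvalue


class SingularMatrixError(PairpathError):
    """A correlation matrix is singular or too ill-conditioned to invert."""

    def __init__(self, message: str, condition_number: float | None = None):
        super().__init__(message)
        self.condition_number = condition_number


class EstimationError(PairpathError):
    """A model estimator failed (non-convergence, degenerate input, ...)."""

    def __init__(self, message: str, lam: float | None = None,
                 n_iter: int | None = None):
        super().__init__(message)
        self.lam = lam
        self.n_iter = n_iter


class NoPathsError(PairpathError):
    """A path-level query was made for a pair with no usable paths."""
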