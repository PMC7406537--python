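"""Exception hierarchy for mixls."""


class MixLSError(Exception):
    """Base class for all mixls errors."""


class DataError(MixLSError):
    """Invalid input data (parse failures, sort-order violations, bad codes)."""


class SortOrderError(DataError):
    """Rows are not contiguous by subject ID."""


class MissingCodeError(DataError):
    """Invalid missing-value code (must be a non-zero real number)."""


class SpecificationError(MixLSError):
    """Invalid model specification."""


class ConvergenceError(MixLSError):
    """Optimizer failed to converge.

    Carries the last iterate and the gradient norm at that point so the
    user can diagnose (e.g. restart with a ridge or fewer parameters).
    """

    def __init__(self, message, params=None, grad_norm=None, iterations=None):
        super().__init__(message)
        self.params = params
        self.grad_norm = grad_norm
        self.iterations = iterations


class RankError(MixLSError):
    """Singular information or design matrix (collinearity)."""


class NumericError(MixLSError):
    """Numerical degeneracy (underflow, non-finite values)."""
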