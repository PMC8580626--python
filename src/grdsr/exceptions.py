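"""Exception hierarchy for grdsr."""


class GrdsrError(Exception):
    """Base class for all grdsr-specific errors."""


class NumericalError(GrdsrError):
    """A computation produced non-finite values or an unusable system."""


class ConvergenceError(GrdsrError):
    """An iterative solver failed to reach its stopping criterion.

    Attributes
    ----------
    last_iterate : ndarray or None
        The solver state when the iteration budget ran out.
    residual : float or None
        The optimality (KKT) residual at the last iterate.
    """

    def __init__(self, message, last_iterate=None, residual=None):
        super().__init__(message)
        self.last_iterate = last_iterate
        self.residual = residual


class NotFittedError(GrdsrError):
    """A fitted model was required but the model has not been fitted."""
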