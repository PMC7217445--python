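"""Exception types shared across the package."""


class OvichoiceError(Exception):
    """Base class for package errors."""


class InvalidInputError(OvichoiceError, ValueError):
    """An argument violates a documented precondition."""


class InfeasibleDesignError(OvichoiceError):
    """No regular fraction of the requested resolution exists at this run size.

    Attributes
    ----------
    best_resolution : int or None
        The highest resolution achievable at the requested run size, when known.
    """

    def __init__(self, message, best_resolution=None):
        super().__init__(message)
        self.best_resolution = best_resolution


class SchemaError(OvichoiceError, ValueError):
    """A file is missing required columns or contains unparseable values."""


class ConvergenceError(OvichoiceError, RuntimeError):
    """An optimizer failed to converge; carries the best iterate found."""

    def __init__(self, message, best_params=None, grad_norm=None):
        super().__init__(message)
        self.best_params = best_params
        self.grad_norm = grad_norm
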