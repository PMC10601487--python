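"""Exception types shared across the package."""


class MrckitError(Exception):
    """Base class for all package errors."""


class InvalidInputError(MrckitError, ValueError):
    """Malformed or inconsistent user input."""


class InvalidDensityError(MrckitError, ValueError):
    """A spectral density that cannot be discretized (e.g. divergent J/omega)."""


class NotEmbeddableError(MrckitError, ValueError):
    """A reorganization-energy matrix whose Gram matrix is not positive
    semidefinite, so no point configuration reproduces it."""


class NumericalFailureError(MrckitError, RuntimeError):
    """A numerical procedure (root bracketing, eigensolve) failed."""


class EstimatorDegenerateError(MrckitError, RuntimeError):
    """A trajectory-ensemble estimator with no usable samples."""
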