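"""Exception hierarchy shared across the package."""


class MethnetError(Exception):
    """Base class for all package-specific errors."""


class DegenerateInputError(MethnetError):
    """A variable (or joint system) is numerically degenerate.

    Raised when a covariance matrix stays singular after regularization,
    e.g. a constant vector or two bit-identical columns, so that the
    Gaussian information estimators are undefined.
    """

    def __init__(self, message: str, variable_ids: tuple = ()):  # noqa: D107
        super().__init__(message)
        self.variable_ids = tuple(variable_ids)


class ValidationError(MethnetError):
    """Input data violates a documented contract (shape, range, ids)."""
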