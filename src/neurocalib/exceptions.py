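"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """An invalid model, network or training configuration."""


class NumericalInstabilityError(RuntimeError):
    """A solver or training step produced non-finite values."""

    def __init__(self, message: str, step: int | None = None, lambda_hat=None):
        super().__init__(message)
        self.step = step
        self.lambda_hat = lambda_hat


class ConvergenceError(RuntimeError):
    """A fixed-point iteration failed to converge within its step budget."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class DegenerateSampleError(ValueError):
    """Posterior samples carry no usable information (e.g. all losses non-finite)."""
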