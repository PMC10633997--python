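"""Exception hierarchy shared across the package."""


class MolUQError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MolUQError, ValueError):
    """Invalid configuration value (non-positive dimension, bad quantile, ...)."""


class InputError(MolUQError, ValueError):
    """Misaligned, empty, or otherwise malformed input data."""


class DomainError(MolUQError, ValueError):
    """Mathematical domain violation (sigma^2 <= 0, alpha <= 1, zero vector, ...)."""


class UnsupportedModelError(MolUQError, TypeError):
    """A model handle does not expose what the operation requires."""


class TrainingDivergenceError(MolUQError, RuntimeError):
    """Loss became non-finite during training."""


class DegenerateError(MolUQError, ValueError):
    """Degenerate statistic: zero variance, zero weights, RMV=0 bin, constant vector."""


class InfeasibleSampleError(MolUQError, ValueError):
    """A stratified sample cannot be drawn; carries the offending strata."""

    def __init__(self, message: str, empty_strata=()):
        super().__init__(message)
        self.empty_strata = tuple(empty_strata)
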