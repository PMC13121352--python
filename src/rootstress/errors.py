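"""Exception hierarchy shared by all pipeline stages."""


class RootstressError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(RootstressError, ValueError):
    """An argument violates a documented precondition."""


class DomainError(RootstressError, ValueError):
    """Input lies outside the mathematical domain of a model (e.g. w <= 0
    fed to a power law with a negative water-content exponent)."""


class DegenerateDesignError(RootstressError, ValueError):
    """The data lack the spread needed to identify the model parameters
    (constant regressor, too few distinct levels, too few rows)."""


class DegenerateInputError(RootstressError, ValueError):
    """Input is structurally valid but carries no usable signal
    (e.g. all-zero elongation rates with no external reference)."""


class ConvergenceError(RootstressError, RuntimeError):
    """The nonlinear solver failed to converge; carries the last iterate
    or the list of tried starts where available."""

    def __init__(self, message, last_iterate=None, tried_starts=None):
        super().__init__(message)
        self.last_iterate = last_iterate
        self.tried_starts = tried_starts


class UndefinedMetricError(RootstressError, ValueError):
    """An agreement metric is mathematically undefined on these inputs
    (zero variance, zero observed sum, zero potential error)."""


class SchemaError(RootstressError, ValueError):
    """A tabular input is missing required columns."""

    def __init__(self, missing, message=None):
        self.missing = list(missing)
        super().__init__(message or f"missing required column(s): {', '.join(self.missing)}")


class ConfigError(RootstressError, ValueError):
    """A pipeline or generator configuration is incomplete or inconsistent."""


class StageError(RootstressError, RuntimeError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage, original):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}' failed: {original}")
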