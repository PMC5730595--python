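"""Exception types shared across the package."""


class NoiseTissueError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(NoiseTissueError, ValueError):
    """A kinetic rate, distribution parameter, or config value is invalid."""


class SchemaError(NoiseTissueError, ValueError):
    """An input table does not match the documented CSV schema."""


class EstimationError(NoiseTissueError, RuntimeError):
    """An estimator has no defined value on the given data."""


class UndefinedCorrelationError(EstimationError):
    """Correlation requested on degenerate (zero-variance) input."""


class NormalizationStateError(NoiseTissueError, ValueError):
    """A table operation was applied in the wrong normalization state."""
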