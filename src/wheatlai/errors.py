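"""Exception hierarchy. CLI maps ConfigError -> exit 2, DataError -> exit 3."""


class WheatLAIError(Exception):
    """Base class for all package errors."""


class ParameterDomainError(WheatLAIError, ValueError):
    """A model parameter is outside its physical/prior domain."""


class DataError(WheatLAIError, ValueError):
    """Malformed or inconsistent input data (grids, rasters, tables)."""


class ConfigError(WheatLAIError, ValueError):
    """Invalid run configuration (degenerate priors, bad fractions, ...)."""


class UndefinedIndexError(WheatLAIError, ArithmeticError):
    """A vegetation index is undefined for the given band values."""


class UndefinedCostError(WheatLAIError, ArithmeticError):
    """The inversion cost is undefined (observed value below the eps guard)."""


class InversionFailedError(WheatLAIError, RuntimeError):
    """No LUT entry yields a defined cost for the observation."""
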