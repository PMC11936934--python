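"""Exception hierarchy shared across the toolkit."""


class NeurostageError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(NeurostageError, ValueError):
    """An argument violates a documented precondition."""


class ShapeError(NeurostageError, ValueError):
    """Operand shapes are inconsistent."""


class NumericError(NeurostageError, ValueError):
    """A numerically invalid operand (e.g. zero atmospheric light)."""


class DataError(NeurostageError, ValueError):
    """Dataset contents violate a contract (empty class, single-class labels...)."""


class ConfigError(NeurostageError, ValueError):
    """A configuration value is unusable (unknown backbone, head-count mismatch...)."""
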