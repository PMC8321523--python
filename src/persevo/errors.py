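"""Shared exception and warning types."""


class PersevoError(Exception):
    """Base class for package errors."""


class InvalidParameterError(PersevoError, ValueError):
    """A parameter violates a documented precondition."""


class ExtinctionError(PersevoError, RuntimeError):
    """An operation that requires live cells was applied to an empty population."""


class UndefinedInputError(PersevoError, ValueError):
    """Inputs for which the requested quantity is mathematically undefined."""


class UndefinedCoefficientError(UndefinedInputError):
    """Competition coefficient undefined (monoculture AUC equals ancestor AUC)."""


class ConstantInputError(UndefinedInputError):
    """Correlation undefined because one input vector is constant."""


class SchemaError(PersevoError, ValueError):
    """A tabular file does not match its declared schema."""


class SterileCultureWarning(UserWarning):
    """Zero survivors observed; fraction is an upper-censored estimate."""


class FractionAboveOneWarning(UserWarning):
    """Post-treatment count exceeded pre-treatment count (counting noise)."""


class BoundaryFitnessWarning(UserWarning):
    """Relative fitness hit a frequency boundary (0 or 1); value is degenerate."""
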