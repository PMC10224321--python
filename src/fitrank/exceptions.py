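"""Exception hierarchy shared across the package."""


class FitrankError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(FitrankError, ValueError):
    """A simulation or experiment configuration violates its preconditions."""


class DegenerateLibraryError(InvalidConfigError):
    """The configured library admits no sequence diversity."""


class UnsupportedPoolError(FitrankError, ValueError):
    """A read-count operation was applied to a pool it is not defined for."""


class LengthMismatchError(FitrankError, ValueError):
    """Sequences of unequal length were compared where hamming distance is undefined."""


class RaggedLengthError(LengthMismatchError):
    """An encoder requiring fixed-length input received ragged sequences."""


class InvalidThresholdError(FitrankError, ValueError):
    """Stability class thresholds overlap or are inverted."""


class AdapterError(FitrankError, RuntimeError):
    """An embedding adapter failed; carries sequence-index context."""


class SingleClassError(FitrankError, ValueError):
    """A classifier was asked to train on labels containing a single class."""


class ConstantTargetError(FitrankError, ValueError):
    """R^2 is undefined for a constant target; the MSE is still carried."""

    def __init__(self, message: str, mse: float | None = None):
        super().__init__(message)
        self.mse = mse


class DegenerateMatrixError(FitrankError, ValueError):
    """A decision matrix admits no discrimination between alternatives."""


class MissingCellsError(FitrankError, ValueError):
    """The replicate table is missing (alternative, seed) cells."""


class UndefinedStatisticError(FitrankError, ValueError):
    """A test statistic is undefined for the supplied groups."""
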