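"""Exception hierarchy shared across the package."""


class RTWalkError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(RTWalkError, ValueError):
    """A model or configuration parameter is outside its valid domain."""


class ConnectivityError(RTWalkError, RuntimeError):
    """No open path from the origin to the absorbing boundary.

    Carries ``rejections``: how many grid realizations were discarded
    before giving up.
    """

    def __init__(self, message: str, rejections: int = 0):
        super().__init__(message)
        self.rejections = rejections


class RunawayWalkError(RTWalkError, RuntimeError):
    """A walker exceeded the per-walk step cap (mis-specified grid)."""

    def __init__(self, message: str, walk_index: int = -1):
        super().__init__(message)
        self.walk_index = walk_index


class BinningError(RTWalkError, ValueError):
    """Histogram operands do not share bin edges."""


class EmptyInputError(RTWalkError, ValueError):
    """An operation received an empty sample set."""


class DivergenceUndefinedError(RTWalkError, ValueError):
    """KL divergence undefined: P has support where Q has none."""


class FitFailureError(RTWalkError, RuntimeError):
    """Every optimizer start failed to improve on the initial objective."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


class InvalidWindowError(RTWalkError, ValueError):
    """A tail-estimation window is empty or outside the support."""


class InsufficientPopulationError(RTWalkError, ValueError):
    """A population-level analysis needs more players/records."""
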