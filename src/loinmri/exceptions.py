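"""Exception types shared across the package."""


class LoinMRIError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(LoinMRIError, ValueError):
    """A phantom specification violates its geometric or range constraints."""


class EmptyForegroundError(LoinMRIError, ValueError):
    """Segmentation produced no foreground pixel."""


class ROITooSmallError(LoinMRIError, ValueError):
    """The region of interest is smaller than one tile."""


class NoPairsError(LoinMRIError, ValueError):
    """A region or matrix is too small to form any neighbouring pixel pair."""


class SingularFitError(LoinMRIError, ValueError):
    """An unpenalized least-squares fit is rank deficient."""


class DegenerateDataError(LoinMRIError, ValueError):
    """Input data carry no variation where variation is required."""


class ContractError(LoinMRIError, ValueError):
    """An argument violates a documented precondition."""
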