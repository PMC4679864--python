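"""Exception types shared across the pipeline."""


class MvpaError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(MvpaError, ValueError):
    pass


class DesignInfeasibleError(MvpaError):
    """Trial-sequence constraints cannot be satisfied."""


class UnknownRegionError(MvpaError, KeyError):
    """A code or disruption factor references a region id with no mask."""


class ShapeError(MvpaError, ValueError):
    pass


class EmptyDesignError(MvpaError):
    """No stimulus events to build regressors from."""


class RankDeficiencyError(MvpaError):
    """Design matrix is rank deficient; message names the collinear columns."""


class AmbiguousWindowError(MvpaError):
    """A lag window selects zero or more than one volume for some trial."""


class PairingError(MvpaError):
    """Run-pair cross-validation folds cannot be constructed."""


class InvalidFoldError(MvpaError):
    """A training fold contains a single class."""


class ConvergenceError(MvpaError):
    """Iterative optimisation failed to reach the gradient tolerance."""


class AlignmentError(MvpaError):
    """Permutation sets are not matched across subjects or conditions."""


class UndefinedCorrelationError(MvpaError):
    """Rank correlation is undefined (constant input)."""


class InsufficientGroupError(MvpaError):
    """A median-split group has fewer than two members."""
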