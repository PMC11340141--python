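"""Exception hierarchy for distrand."""


class DistrandError(Exception):
    """Base class for all distrand-specific errors."""


class DegenerateDesignError(DistrandError, ValueError):
    """Every combinatorial arm is infeasible (total unnormalized mass is 0)."""


class AmbiguousEffectError(DistrandError, ValueError):
    """Two same-size effect rules match an arm with conflicting success probabilities."""


class UndefinedContrastError(DistrandError, ValueError):
    """An intervention is never (or always) allocated, so receivers-vs-non-receivers
    contrasts do not exist."""


class RankDeficientModelError(DistrandError, ValueError):
    """The requested regression design matrix is rank-deficient (e.g. duplicated columns)."""


class NonIdentifiableFitError(DistrandError, RuntimeError):
    """The probit power-curve cannot be fit (all observed outcomes identical)."""


class SearchFailureError(DistrandError, RuntimeError):
    """The adaptive sample-size search could not obtain an identifiable history."""
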