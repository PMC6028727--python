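"""Error taxonomy for chain-stage failures.

Every processing stage raises a :class:`ChainStageError` subclass when it
cannot produce a valid output for a given matrix.  The chain engine catches
these and records them as structured failures (stage + error class) instead
of aborting a sweep, so that per-dataset failure accounting is possible.
"""

from __future__ import annotations


class ValidationError(ValueError):
    """Input object violates a structural invariant (not a chain failure)."""


class ChainStageError(RuntimeError):
    """A processing stage could not be applied to this matrix."""

    #: machine-readable error class used in failure bookkeeping
    failure_class: str = "error"

    def __init__(self, message: str, stage: str):
        super().__init__(message)
        self.stage = stage


class DomainError(ChainStageError):
    """Values outside the method's mathematical domain (e.g. log of <= 0)."""

    failure_class = "domain-error"


class DegenerateScaleError(ChainStageError):
    """A scale statistic needed for normalization is exactly zero."""

    failure_class = "degenerate-scale"


class InsufficientOverlapError(ChainStageError):
    """Too few co-observed features between samples (e.g. TMM reference)."""

    failure_class = "insufficient-overlap"


class InsufficientDataError(ChainStageError):
    """Not enough complete observations to estimate the model."""

    failure_class = "insufficient-data"


class NonConvergenceError(ChainStageError):
    """An iterative fit diverged or failed numerically."""

    failure_class = "non-convergence"


class AssessmentError(ChainStageError):
    """Precision metric undefined for this output (no eligible replicates)."""

    failure_class = "assessment-error"

    def __init__(self, message: str):
        super().__init__(message, stage="assessment")
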