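"""Exception hierarchy shared across the package.

Every error raised deliberately by this package derives from
:class:`PhyloConsensusError`, so callers (and the CLI) can catch one type.
"""


class PhyloConsensusError(Exception):
    """Base class for all errors raised by phyloconsensus."""


class AlignmentError(PhyloConsensusError):
    """The alignment is structurally broken (e.g. rows of unequal length)."""


class ValidationError(PhyloConsensusError):
    """An input violates a documented invariant (ids, characters, matrices)."""


class InsufficientFamilyError(PhyloConsensusError):
    """Fewer than three sequences survive filtering; consensus is meaningless."""


class UndefinedDistanceError(PhyloConsensusError):
    """A pairwise distance cannot be computed (e.g. an all-gap sequence)."""


class TreeError(PhyloConsensusError):
    """A tree operation received a tree that violates its precondition."""


class MappingError(PhyloConsensusError):
    """Sequence-to-structure numbering disagrees with the structure contents."""


class ConfigError(PhyloConsensusError):
    """A configuration value is missing or out of range."""


class NoDecayError(PhyloConsensusError):
    """A thermal-inactivation series shows no decay (non-negative slope)."""


class FitError(PhyloConsensusError):
    """A nonlinear fit failed to converge or the data violate its shape."""

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = residuals


class StageError(PhyloConsensusError):
    """A pipeline stage failed; carries the stage name and the original cause."""

    def __init__(self, stage, cause):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
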