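"""Exception types shared across the package."""


class MevaeError(Exception):
    """Base class for package errors."""


class ConfigurationError(MevaeError):
    """A spec/config violates its invariants (bad counts, shapes, ranges)."""


class InvalidInputError(MevaeError):
    """An input array violates a precondition (empty mask, shape mismatch...)."""


class ProvenanceError(MevaeError):
    """A training pair was assembled from the wrong images."""


class TrainingDiverged(MevaeError):
    """A loss term became non-finite during training."""


class PipelineError(MevaeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
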