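"""Exception types shared across the package."""


class GbneaError(Exception):
    """Base class for all package-specific errors."""


class DataValidationError(GbneaError, ValueError):
    """Malformed or inconsistent input data."""


class NoOverlapError(GbneaError, ValueError):
    """A gene set shares no genes with the network universe."""


class PipelineStageError(GbneaError, RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage
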