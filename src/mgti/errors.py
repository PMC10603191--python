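"""Exception hierarchy shared across the pipeline stages."""


class MgtiError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MgtiError, ValueError):
    """An invalid parameter value or inconsistent configuration."""


class FormatError(MgtiError, ValueError):
    """A malformed input file (OBO, TSV) or structurally invalid graph."""


class DomainError(MgtiError, ValueError):
    """An input outside the mathematical domain of an operation."""


class PipelineError(MgtiError, RuntimeError):
    """A stage-level failure while orchestrating the pipeline."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
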