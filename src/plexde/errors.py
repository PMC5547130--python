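"""Exception types shared across the pipeline."""


class PlexdeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PlexdeError, ValueError):
    """A configuration object violates one of its invariants."""


class DesignError(PlexdeError, ValueError):
    """An experiment design is inconsistent (channels, GIS, duplicate samples)."""


class PipelineError(PlexdeError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
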