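"""Exception hierarchy shared across the package."""


class GaitwalkError(Exception):
    """Base class for all package errors."""


class ValidationError(GaitwalkError):
    """Input violates a documented invariant (bad enum, non-monotone time, ...)."""


class ParseError(GaitwalkError):
    """A plain-text input file could not be parsed."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class InsufficientGaitError(GaitwalkError):
    """Too few gait cycles were detected to analyse a recording."""


class PipelineStageError(GaitwalkError):
    """Wraps a failure inside run_pipeline with stage and recording context."""

    def __init__(self, stage: str, recording_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on recording {recording_id!r}: {cause}")
        self.stage = stage
        self.recording_id = recording_id
        self.cause = cause
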