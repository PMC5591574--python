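"""Error hierarchy shared across the package.

Every error raised by eyescript derives from :class:`EyescriptError`, so callers
can catch one base type.  Argument/contract violations additionally derive from
``ValueError`` (or ``RuntimeError`` for state errors) to stay idiomatic.
"""


class EyescriptError(Exception):
    """Base class for all eyescript errors."""


class ArgumentError(EyescriptError, ValueError):
    """A function argument violates its contract."""


class ConfigurationError(EyescriptError, ValueError):
    """A channel layout / pipeline configuration is inconsistent."""


class FormatError(EyescriptError, ValueError):
    """A file's payload cannot be parsed as the expected format."""


class DatasetError(EyescriptError, ValueError):
    """A dataset manifest references missing or inconsistent entries."""


class DegenerateTraceError(EyescriptError, ValueError):
    """A trace is empty or has zero path length and cannot be processed."""


class EstimationError(EyescriptError, ValueError):
    """A regression/estimation step is ill-posed (e.g. zero variance)."""


class TrainingError(EyescriptError, ValueError):
    """Classifier training is impossible on the given data."""


class StateError(EyescriptError, RuntimeError):
    """An object is used before it was fitted/initialised."""


class PipelineStageError(EyescriptError, RuntimeError):
    """A reconstruction stage failed; carries the stage name."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"pipeline stage '{stage}' failed: {original}")
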