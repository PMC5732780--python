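"""Exception hierarchy shared across the package."""


class LpiError(Exception):
    """Base class for all package-specific errors."""


class InputError(LpiError, ValueError):
    """Invalid argument values, shapes, or domain violations."""


class ParseError(InputError):
    """Malformed on-disk input; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DegenerateInputError(InputError):
    """Input that is syntactically valid but makes the computation ill-posed
    (e.g. a sequence whose self-alignment score is zero)."""


class ModelError(LpiError):
    """Model state errors, e.g. smoothing requested with no positive entities."""


class PipelineError(LpiError):
    """A pipeline stage failed; message is prefixed with the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"[{stage}] {cause}")
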