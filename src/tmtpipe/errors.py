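"""Exception hierarchy with stable exit codes for the CLI."""


class TmtPipeError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class FormatError(TmtPipeError):
    """A file does not follow its declared dialect."""

    exit_code = 2


class DesignError(TmtPipeError):
    """Channel-design table inconsistent with the data or with itself."""

    exit_code = 3


class InputError(TmtPipeError):
    """Operation received semantically invalid input."""

    exit_code = 4


class InsufficientDataError(TmtPipeError):
    """Too few observations survive for the requested computation."""

    exit_code = 5


class DegenerateDataError(TmtPipeError):
    """Degenerate numeric input (zero-total channel, non-finite values)."""

    exit_code = 6


class ConfoundingError(TmtPipeError):
    """Batch is confounded with the biological grouping."""

    exit_code = 7


class ConfigError(TmtPipeError):
    """Pipeline configuration invalid or incomplete."""

    exit_code = 8


class PlanError(TmtPipeError):
    """A pairing plan references a comparison that does not exist."""

    exit_code = 9


class StageError(TmtPipeError):
    """A pipeline stage failed; carries the stage name."""

    exit_code = 10

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
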