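"""Exception hierarchy for veinseg."""


class VeinsegError(Exception):
    """Base class for all veinseg errors."""


class ValidationError(VeinsegError):
    """An input violated a documented precondition."""


class ConvergenceError(VeinsegError):
    """An iterative procedure did not reach its fixpoint within the budget."""


class StageError(VeinsegError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
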