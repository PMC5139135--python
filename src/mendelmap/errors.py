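"""Exception types shared across the pipeline."""


class MendelmapError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MendelmapError):
    """A simulation or run configuration violates its invariants."""


class UndefinedResultError(MendelmapError):
    """A statistic has no defined value on the given input (e.g. empty denominator)."""


class StageError(MendelmapError):
    """A pipeline stage failed; carries the stage name and a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code
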