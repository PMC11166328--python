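"""Exception hierarchy; the CLI maps these onto exit codes."""


class TribekitError(Exception):
    """Base class for all package errors."""


class ConfigError(TribekitError):
    """Invalid configuration or parameters (CLI exit code 2)."""


class DataError(TribekitError):
    """Malformed or inconsistent input data (CLI exit code 3)."""


class StageError(TribekitError):
    """A pipeline stage failed; names the stage and the offending input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
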