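"""Exception hierarchy.

``ValidationError`` signals bad user input or configuration (CLI exit code 2);
``StageError`` signals a pipeline stage failure (CLI exit code 3).
"""


class HaploscanError(Exception):
    """Base class for all package errors."""


class ValidationError(HaploscanError):
    """Invalid input data, parameters or configuration."""


class PedigreeError(ValidationError):
    """Impossible or inconsistent pedigree specification."""


class WindowError(ValidationError):
    """A scan window contains no markers (window too small)."""


class StageError(HaploscanError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
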