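"""Exception hierarchy shared by all pipeline stages.

Validation problems (bad tables, impossible parameters) and stage failures
are distinguished so the command line can map them to distinct exit codes
(2 and 3 respectively).
"""


class CoexpAtlasError(Exception):
    """Base class for all package errors."""


class ValidationError(CoexpAtlasError):
    """Invalid input data or parameters (CLI exit code 2)."""


class FormatError(ValidationError):
    """Malformed input file: duplicate ids, missing columns, bad values."""


class StageError(CoexpAtlasError):
    """A pipeline stage failed mid-run (CLI exit code 3)."""

    def __init__(self, stage: str, cause: str):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
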