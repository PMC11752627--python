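"""Exception hierarchy shared by all afwave modules."""


class AfwaveError(Exception):
    """Base class for all toolkit errors."""


class InputError(AfwaveError):
    """The supplied data is unusable (missing, empty, wrong shape)."""


class FormatError(AfwaveError):
    """A file or value violates the expected on-disk format."""


class ParameterError(AfwaveError, ValueError):
    """A configuration parameter is out of its valid range."""


class StageError(AfwaveError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
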