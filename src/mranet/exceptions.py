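"""Exception types shared across the package."""


class MranetError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(MranetError, ValueError):
    """A caller-supplied parameter is out of its valid range."""


class InvalidInputError(MranetError, ValueError):
    """An input object (matrix, vector, gene set) violates a precondition."""


class InvalidStageError(MranetError, ValueError):
    """A network was passed to an operation that expects a different stage."""


class PipelineStageError(MranetError, RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnosis."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
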