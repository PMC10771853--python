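"""Exception types shared across the package."""


class EpiResponseError(Exception):
    """Base class for all package errors."""


class ValidationError(EpiResponseError, ValueError):
    """Raised when input data violates a documented contract."""


class SchemaError(EpiResponseError, ValueError):
    """Raised when tabular inputs are malformed (columns, ids, alignment)."""


class PipelineStageError(EpiResponseError, RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage
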