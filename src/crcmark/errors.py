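"""Exception types shared across the pipeline stages."""


class CrcmarkError(Exception):
    """Base class for all package errors."""


class ConfigError(CrcmarkError):
    """Invalid cohort or pipeline configuration."""


class SchemaError(CrcmarkError):
    """An input table is missing required columns or violates a contract."""

    def __init__(self, message: str, path: str | None = None):
        self.path = path
        super().__init__(message if path is None else f"{path}: {message}")


class CalibrationError(CrcmarkError):
    """A PCR run cannot be calibrated (no shared inter-run calibrator)."""


class StageError(CrcmarkError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
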