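"""Exception hierarchy shared across the pipeline.

Config problems and data problems are distinct branches so the CLI can map
them to distinct exit codes (2 and 3 respectively).
"""


class ArrayCascadeError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(ArrayCascadeError):
    """A parameter or configuration value is outside its documented domain."""


class DataError(ArrayCascadeError):
    """Input data violate a structural precondition."""


class SchemaError(DataError):
    """A table is missing mandatory columns or has mismatched column pairs."""


class IntegrityError(DataError):
    """Duplicate identifiers or other internal inconsistencies."""


class PipelineError(ArrayCascadeError):
    """A pipeline stage could not proceed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


class InvalidCurveError(DataError):
    """A qPCR standard curve has a non-negative slope (no amplification)."""
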