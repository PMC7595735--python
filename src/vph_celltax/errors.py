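"""Exception types shared across the pipeline."""


class CellTaxError(Exception):
    """Base class for all package errors."""


class FormatError(CellTaxError):
    """An on-disk artifact violates the expected file format."""


class SpecError(CellTaxError):
    """A simulation specification violates its own invariants."""


class ConfigurationError(CellTaxError):
    """A configuration value (method name, missing annotation, backend) is invalid."""


class EmptyCohortError(CellTaxError):
    """A filtering stage removed every cell."""


class DegenerateFitError(CellTaxError):
    """A mixture model cannot be fit because the observations have zero spread."""


class AmbiguousMappingError(CellTaxError):
    """Component-to-class naming is not injective (tied component means)."""


class StageError(CellTaxError):
    """A pipeline stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
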