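"""Exception hierarchy shared across the pipeline."""


class NanoQSTRError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(NanoQSTRError):
    """A required column is missing or a matrix schema does not match."""


class RowParseError(NanoQSTRError):
    """A data cell could not be parsed; carries the offending row index."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class EmptyDatasetError(NanoQSTRError):
    """The input file or dataset contains no data rows."""


class FormulaParseError(NanoQSTRError):
    """A core composition label could not be parsed as a chemical formula."""


class ElementLookupError(NanoQSTRError):
    """An element symbol is absent from the embedded element table."""


class ConstantColumnError(NanoQSTRError):
    """A transform that requires non-zero spread met a constant column."""


class MetricError(NanoQSTRError):
    """A validation metric is undefined for the given inputs."""


class ConfigError(NanoQSTRError):
    """A pipeline or generator configuration failed validation."""


class LeakError(NanoQSTRError):
    """Rows reserved for prospective evaluation were used in fitting."""


class StageError(NanoQSTRError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
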