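"""Exception types shared across the package."""


class DsbAtlasError(Exception):
    """Base class for all package errors."""


class MalformedRecordError(DsbAtlasError):
    """A text record (BED line, TSS row, ...) violates the expected format."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class CorruptChainError(DsbAtlasError):
    """Chain header spans disagree with the block-sum arithmetic."""


class AmbiguousMappingError(DsbAtlasError):
    """Several chains cover one base under the strict 'reject' policy."""


class IncompatibleSetsError(DsbAtlasError):
    """Two collections live on different assemblies and cannot be compared."""


class UndefinedFractionError(DsbAtlasError):
    """A percentage was requested with a zero denominator."""


class InsufficientPairsError(DsbAtlasError):
    """Too few paired observations for a rank correlation."""


class SpecInfeasibleError(DsbAtlasError):
    """Simulation parameters cannot be realised (placement failed)."""


class ConfigurationError(DsbAtlasError):
    """Pipeline inputs are mutually inconsistent (e.g. assembly labels)."""
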