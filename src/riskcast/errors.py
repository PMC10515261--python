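"""Exception hierarchy.

Every error raised by the package derives from :class:`RiskcastError`, so
callers (and the pipeline runner) can catch one base class. Names mirror the
failure modes of each stage: schema/parse/integrity for ingestion, limits for
hazard scaling, window for conditional-exceedance counting, and so on.
"""


class RiskcastError(Exception):
    """Base class for all riskcast errors."""


class SchemaError(RiskcastError):
    """A mandatory column is missing or the schema mapping is invalid."""


class ParseError(RiskcastError):
    """A cell could not be parsed; message carries the offending row index."""


class IntegrityError(RiskcastError):
    """Duplicate (region, year) observations or similar uniqueness violation."""


class CoverageError(RiskcastError):
    """Population (or other lookup) missing for observed (region, year) pairs."""


class LimitsError(RiskcastError):
    """Hazard limit missing or non-positive for a region present in the panel."""


class EmptyInputError(RiskcastError):
    """An operation received a series/panel with no usable data."""


class WindowError(RiskcastError):
    """Conditioning number k exceeds the number of merged events."""


class InsufficientTailError(RiskcastError):
    """Fewer than the minimum usable grid points above the cut-on level."""


class InversionError(RiskcastError):
    """Target probability outside the invertible range of a fitted tail."""


class DegenerateSampleError(RiskcastError):
    """A constant (zero-variance) sample cannot support a distribution fit."""


class ConfigError(RiskcastError):
    """Invalid simulation or pipeline configuration."""


class UnsupportedOracleError(RiskcastError):
    """Closed-form truth requested outside the i.i.d. regime where it exists."""


class DomainError(RiskcastError):
    """Argument outside its mathematical domain (e.g. non-positive period)."""


class PipelineStageError(RiskcastError):
    """Wraps a stage failure with the stage name and a remediation hint."""

    def __init__(self, stage: str, original: Exception, hint: str = ""):
        self.stage = stage
        self.original = original
        self.hint = hint
        msg = f"pipeline stage '{stage}' failed: {original}"
        if hint:
            msg += f" (hint: {hint})"
        super().__init__(msg)
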