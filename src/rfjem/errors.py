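"""Exception types shared across the package."""


class RfJemError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(RfJemError):
    """An input table violates its declared schema (missing column, bad value)."""


class DuplicateKeyError(SchemaError):
    """Two rows claim the same (isco88, field_kind) cell of the matrix."""


class InvalidMeasurementError(RfJemError):
    """A source measurement violates its physical constraints."""


class UndefinedThresholdError(RfJemError):
    """No exposed entries exist, so a median prevalence cannot be defined."""


class OrphanSpellError(SchemaError):
    """A job spell references a participant id absent from the participant table."""


class DataError(RfJemError):
    """A record is internally inconsistent (e.g. case without diagnosis year)."""


class ContractViolation(RfJemError):
    """An operation received input that an upstream stage should have removed."""


class UndefinedCutpointsError(RfJemError):
    """No exposed controls exist, so percentile cut-points cannot be defined."""


class NotConvergedError(RfJemError):
    """A model fit did not converge; downstream summaries refuse to run."""


class InestimableRunError(RfJemError):
    """A filter or configuration left no cases or no controls to analyse."""
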