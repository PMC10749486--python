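"""Exception hierarchy shared across the package."""


class SeropanelError(Exception):
    """Base class for all package errors."""


class SchemaError(SeropanelError):
    """A required column or marker could not be resolved in an input table."""


class InputError(SeropanelError):
    """An input file is empty, unreadable, or structurally invalid."""


class CohortValidationError(SeropanelError):
    """A cohort violates a structural invariant (e.g. duplicate sample ids)."""


class FitError(SeropanelError):
    """A reference model could not be fitted (e.g. fewer than two HD values)."""


class ConfigError(SeropanelError):
    """An analysis was requested with an inconsistent configuration."""


class StandardizationError(SeropanelError):
    """Z-scoring is impossible (zero reference standard deviation)."""


class InfeasibleTargetError(SeropanelError):
    """A calibration target pair lies outside the attainable frontier."""
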