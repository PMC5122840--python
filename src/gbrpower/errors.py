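"""Exception hierarchy for gbrpower.

All package-specific failures derive from :class:`GbrPowerError` so callers
can catch one base class; the subclasses mirror the distinct failure modes of
trial design (infeasible recruitment), data generation (calibration,
degenerate inputs) and model fitting.
"""


class GbrPowerError(Exception):
    """Base class for all gbrpower errors."""


class InvalidConfigurationError(GbrPowerError, ValueError):
    """A scenario or panel parameter is outside its valid domain."""


class InfeasibleDesignError(GbrPowerError, ValueError):
    """The requested trial cannot be recruited from the sampling frame."""


class CalibrationError(GbrPowerError, RuntimeError):
    """Baseline-hazard calibration could not bracket a root."""


class DegenerateInputError(GbrPowerError, ValueError):
    """An input has no variation where variation is required."""


class InfeasibleFitError(GbrPowerError, ValueError):
    """The design matrix cannot identify the interaction model."""


class ConfigSchemaError(GbrPowerError, ValueError):
    """A configuration file violates the schema; carries the field name."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"config field '{field}': {message}")
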