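"""Exception hierarchy for repfid."""


class RepfidError(Exception):
    """Base class for all package-specific errors."""


class DomainError(RepfidError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class UnsupportedModelError(RepfidError, ValueError):
    """A closed form was requested for a model family that does not admit it."""


class UndefinedStatisticError(RepfidError, ValueError):
    """A requested statistic (e.g. a correlation) is undefined for the input."""


class InconsistentKineticsError(RepfidError, ValueError):
    """Kinetic parameters contradict each other (e.g. frozen switch with 0<w<1)."""


class CalibrationError(RepfidError, ValueError):
    """Calibration-bead data violate the requirements of the MESF fit."""


class DegenerateDataError(RepfidError, ValueError):
    """Input data are degenerate for the requested estimator."""


class NumericalError(RepfidError, RuntimeError):
    """A numerical routine failed to converge or bracket what it should."""


class ConfigError(RepfidError, ValueError):
    """A study configuration file is malformed or violates its schema."""


class SchemaError(RepfidError, ValueError):
    """A data table does not conform to the expected column dialect."""
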