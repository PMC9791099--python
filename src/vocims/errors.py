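"""Exception hierarchy shared across the package."""


class VocimsError(Exception):
    """Base class for all package errors."""


class InvalidAxisError(VocimsError):
    """An axis is empty or not strictly increasing."""


class OutOfRangeError(VocimsError):
    """A peak center falls outside the grid's axis ranges."""


class ConfigurationError(VocimsError):
    """A cohort design or run configuration is inconsistent."""


class EmptyCropError(VocimsError):
    """A crop window does not intersect the grid."""


class InvalidThresholdError(VocimsError):
    """A negative intensity threshold was requested."""


class IncompatibleGridsError(VocimsError):
    """Samples do not share identical axes."""


class CalibrationError(VocimsError):
    """Threshold calibration could not reach the target."""


class InvalidInputError(VocimsError):
    """Empty or malformed input to a statistical routine."""


class InvalidLabelsError(VocimsError):
    """Labels are not binary or one class is absent."""


class FoldPlanError(VocimsError):
    """A cross-validation fold plan cannot be constructed."""


class FoldDegenerateError(VocimsError):
    """A training fold contains a single class."""


class UndefinedStatisticError(VocimsError):
    """A statistic (e.g. AUC) is undefined for the given labels."""


class SchemaError(VocimsError):
    """A manifest or table has an unexpected schema."""


class ComparisonError(VocimsError):
    """A comparison specification is invalid on the given manifest."""
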