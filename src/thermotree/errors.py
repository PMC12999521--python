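"""Exception hierarchy shared across the package."""


class ThermotreeError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(ThermotreeError):
    """A table is missing required columns or contains unparseable rows."""


class MissingMetadataError(ThermotreeError):
    """Records reference plots or scenarios with no matching metadata."""


class DegenerateDesignError(ThermotreeError):
    """A regression design matrix is rank-deficient (e.g. constant predictor)."""


class OptimizationFailureError(ThermotreeError):
    """A likelihood optimization failed to produce a finite optimum."""


class ImplausibleSensitivityError(ThermotreeError):
    """Knockdown times increase with temperature; no valid z exists."""


class UnknownFamilyError(ThermotreeError):
    """A subtree's family label is not a tip of the backbone tree."""


class ConstraintViolationError(ThermotreeError):
    """Fixed node ages violate the ancestor >= descendant ordering."""


class NumericalDegeneracyError(ThermotreeError):
    """A covariance matrix is singular or not positive definite."""


class EmptyInputError(ThermotreeError):
    """An operation received an empty series or table."""


class InvalidComparisonError(ThermotreeError):
    """Model fits being compared were not computed on identical data."""
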