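"""Exception hierarchy.

Every error raised by this package derives from :class:`OmicsImputeError` so
callers (and the CLI) can distinguish user/data problems from genuine bugs.
"""


class OmicsImputeError(Exception):
    """Base class for all package errors."""


class ParseError(OmicsImputeError):
    """A CSV cell could not be parsed as a number or missing marker."""


class FormatError(OmicsImputeError):
    """Structurally invalid input table (ragged rows, empty table, ...)."""


class IdentifierError(OmicsImputeError):
    """Duplicate sample or feature identifiers."""


class DegenerateOutputError(OmicsImputeError):
    """A filtering step removed every sample or every feature."""


class BudgetError(OmicsImputeError):
    """A missingness simulation budget is 0 cells or the whole pool."""


class CoDependenceError(OmicsImputeError):
    """Co-dependence score undefined (feature group of size 1)."""


class EligibilityError(OmicsImputeError):
    """Dataset too small for imputation-method optimization."""


class OptimizationImpossibleError(OmicsImputeError):
    """No rung of the complete-subset ladder yields an eligible submatrix."""


class HyperparameterError(OmicsImputeError):
    """Infeasible hyperparameter (k >= n_samples, zero iterations, ...)."""


class UninformativeFeatureError(OmicsImputeError):
    """A feature has no observed values to impute from."""


class NeedsCovariatesError(OmicsImputeError):
    """A multivariate imputer was given a single-feature matrix."""


class UndefinedMAPEError(OmicsImputeError):
    """Every holdout truth value was non-positive; MAPE is undefined."""


class UndefinedMomentError(OmicsImputeError):
    """Skewness/kurtosis requested on a zero-variance or too-short vector."""
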