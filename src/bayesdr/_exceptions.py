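"""Exception hierarchy shared across the package."""


class BayesDRError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(BayesDRError):
    """A required column is missing or a design matrix does not match a fit."""


class TreatmentCodingError(BayesDRError):
    """The treatment column cannot be coded to {0, 1}."""


class SupportError(BayesDRError):
    """Common support is violated: an empty treated or control arm, or an
    overlap trim that discards every unit."""


class ConvergenceError(BayesDRError):
    """An iterative fit failed to converge within its iteration budget."""


class SeparationError(ConvergenceError):
    """The propensity model separates treated from control units perfectly;
    the likelihood has no finite maximiser.  Trimming or dropping the
    offending covariate is the usual remedy."""


class SingularDesignError(BayesDRError):
    """The (weighted) design matrix is rank deficient."""
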