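"""Exception hierarchy for registry validation and model fitting."""


class ResusMatchError(Exception):
    """Base class for all package errors."""


class SchemaError(ResusMatchError):
    """A cohort file does not match the documented column dictionary."""


class ParseError(ResusMatchError):
    """A cell could not be parsed into its documented type."""


class IntegrityError(ResusMatchError):
    """A cohort violates a structural invariant (duplicate ids, inconsistent events)."""


class ConfigError(ResusMatchError):
    """A simulation or run configuration is invalid."""


class DegenerateCovariateError(ResusMatchError):
    """A covariate column has zero variance and cannot be estimated."""


class SeparationError(ResusMatchError):
    """The partial likelihood is monotone in some coefficient (perfect separation)."""


class ConvergenceError(ResusMatchError):
    """An iterative fit failed to reach its tolerance."""
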