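"""Exception hierarchy for methdecon."""


class MethdeconError(Exception):
    """Base class for all package errors."""


class ValidationError(MethdeconError, ValueError):
    """Input data violates a documented precondition."""


class IdentifiabilityError(ValidationError):
    """The region-state matrix Z is rank deficient, so cell-type
    proportions are not identifiable."""


class SolverError(MethdeconError, RuntimeError):
    """The constrained quadratic program could not be solved to the
    required KKT tolerance."""
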