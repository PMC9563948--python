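"""Exception hierarchy."""


class LungDRError(Exception):
    """Base class for package errors."""


class SchemaError(LungDRError):
    """A cohort table is missing a required column or has a malformed header."""


class ValidationError(LungDRError):
    """A cohort row violates an invariant (names the offending row)."""


class ConstraintError(LungDRError):
    """A parameter set violates a box bound or stage-ordering constraint."""


class ConfigurationError(LungDRError):
    """A parameter group required by the model spec cannot be resolved."""


class FitError(LungDRError):
    """All optimisation starts failed to converge."""


class SingularHessianError(LungDRError):
    """The observed information matrix is singular at the optimum."""

    def __init__(self, message, null_directions=None):
        super().__init__(message)
        self.null_directions = null_directions
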