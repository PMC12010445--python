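"""Exception types raised across the package."""


class OpmDeployError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(OpmDeployError):
    """A generative parameter is non-finite or outside its domain."""


class AssumptionViolationError(OpmDeployError):
    """A structural assumption of the framework is violated.

    Raised when the historical policy is not constant, or when the
    OPM-informed policy turns out constant (so no treatment decision
    actually depends on the covariate).
    """


class DegenerateOPMError(OpmDeployError):
    """The OPM assigns the same score to both covariate groups."""


class UndefinedAUCError(OpmDeployError):
    """AUC is undefined: one of the outcome classes has zero mass."""
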