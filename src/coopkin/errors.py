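"""Exception hierarchy for coopkin."""


class CoopkinError(Exception):
    """Base class for all coopkin errors."""


class ConfigurationError(CoopkinError):
    """Inconsistent scheme/experiment configuration (e.g. mismatched state labels)."""


class UndefinedAffinityError(CoopkinError):
    """A ligand binds no state, so its apparent affinity is undefined."""


class CannotSaturateError(CoopkinError):
    """The partner ligand binds no state and cannot be driven to saturation."""


class InfeasibleCooperativityError(CoopkinError):
    """Requested cooperativity exceeds what a pure equilibrium shift can produce."""


class UnreachableInhibitionError(CoopkinError):
    """The inhibition floor lies above the requested residual activity."""


class ConvergenceError(CoopkinError):
    """A numerical routine failed to converge within its iteration budget."""


class DegenerateModelError(CoopkinError):
    """All catalytic weights are zero; fractional activity is undefined."""
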