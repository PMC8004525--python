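"""Exception hierarchy for the hyperpredation package."""


class HyperpredationError(Exception):
    """Base class for all package errors."""


class InvalidInputError(HyperpredationError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateModelError(HyperpredationError, ValueError):
    """Model parameters make closed forms undefined (e.g. zero competition)."""


class ClassificationError(HyperpredationError, RuntimeError):
    """Zero or multiple feasible-and-stable equilibria were found.

    Signals parameters on (or numerically indistinguishable from) a
    bifurcation boundary, where the attractor is not uniquely defined.
    """


class ThresholdNotFoundError(HyperpredationError, RuntimeError):
    """No bifurcation threshold exists in the requested bracket."""


class IntegrationError(HyperpredationError, RuntimeError):
    """The ODE integrator failed or produced an invalid trajectory."""


class ConfigError(HyperpredationError, ValueError):
    """A run configuration file failed schema validation."""
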