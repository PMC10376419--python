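"""Exception hierarchy for gutsem.

All package-specific failures derive from :class:`GutsemError` so callers
(and the CLI) can distinguish configuration, data, and numerical problems.
"""


class GutsemError(Exception):
    """Base class for all gutsem errors."""


class ConfigurationError(GutsemError):
    """An invalid configuration value or violated config invariant."""


class FormatError(GutsemError):
    """A malformed input file (bad cell, duplicate identifier, wrong shape)."""


class InsufficientDataError(GutsemError):
    """Too few samples (or groups) to run the requested analysis."""


class DomainError(GutsemError):
    """Input outside an operation's mathematical domain (e.g. all-zero sample)."""


class SpecificationError(GutsemError):
    """A latent-variable model specification that cannot be identified."""


class DegenerateVariableError(GutsemError):
    """A constant (zero-variance) observed variable where variation is required."""


class NonConvergenceError(GutsemError):
    """Optimizer failed to converge; carries the best objective found."""

    def __init__(self, message, best_objective=None):
        super().__init__(message)
        self.best_objective = best_objective


class PruningFailureError(GutsemError):
    """Indicator pruning hit the minimum model size before meeting fit targets."""

    def __init__(self, message, trajectory=None):
        super().__init__(message)
        self.trajectory = trajectory or []


class ResamplingError(GutsemError):
    """SMOTE or fold construction impossible for the given class sizes."""


class NumericalError(GutsemError):
    """A linear-algebra failure (singular or ill-conditioned matrix)."""
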