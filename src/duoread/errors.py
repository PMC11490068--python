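"""Exception hierarchy.

Validation problems (bad arguments, malformed tables) derive from
``ValueError`` so they compose with ordinary Python error handling;
numerical failures during fitting get their own branch.
"""


class DuoreadError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(DuoreadError, ValueError):
    """An argument is outside its documented domain."""


class MalformedDataError(DuoreadError, ValueError):
    """A reading-record table violates the data contract."""


class InvalidPoolError(InvalidArgumentError):
    """A reader pool cannot be paired (odd or too small)."""


class DegenerateRegressionError(InvalidArgumentError):
    """The TPR-on-FPR regression underlying composite scores is undefined."""


class AllExcludedError(DuoreadError):
    """Exclusion criteria removed every reader."""


class NotIdentifiableError(DuoreadError):
    """The likelihood has no unique optimum (no paired data)."""


class DegenerateLikelihoodError(DuoreadError):
    """A marginal rate of exactly 0 or 1 was reached in the likelihood."""


class NonConvergenceError(DuoreadError):
    """The optimizer failed to converge within its iteration budget."""
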