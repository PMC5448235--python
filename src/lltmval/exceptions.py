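"""Exception hierarchy.

All package errors derive from :class:`LltmvalError`; validation problems are
also ``ValueError`` and estimation problems also ``RuntimeError`` so callers
can catch either the package-specific or the generic class.
"""


class LltmvalError(Exception):
    """Base class for all lltmval errors."""


class ValidationError(LltmvalError, ValueError):
    """Invalid input data, dimensions, or configuration."""


class EstimationError(LltmvalError, RuntimeError):
    """Model estimation cannot proceed or did not produce a usable fit."""


class IdentifiabilityError(EstimationError):
    """The LLTM weight matrix plus intercept is rank deficient."""


class NotConvergedError(EstimationError):
    """A fit required by a downstream computation did not converge.

    Scenario loops catch this and record the replicate as non-convergent
    instead of aborting.
    """


class UndefinedCorrelationError(ValidationError):
    """A correlation is requested for a constant parameter vector."""
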