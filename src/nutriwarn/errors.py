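"""Exception hierarchy.

Every error raised on purpose by this package derives from
:class:`NutriwarnError`, so callers can catch one base class at pipeline
boundaries.  Validation errors also derive from :class:`ValueError` to
behave naturally in generic input-checking code.
"""


class NutriwarnError(Exception):
    """Base class for all errors raised by nutriwarn."""


class ConfigurationError(NutriwarnError):
    """A regime/scenario configuration is missing or inconsistent.

    The message always names the offending cell (e.g. ``initial.liquids``)
    so misconfigured threshold tables are diagnosable from the error alone.
    """


class ValidationError(NutriwarnError, ValueError):
    """An input value violates a documented invariant."""


class ScopeError(NutriwarnError):
    """A record outside the scope of the regulation reached the classifier.

    Out-of-scope products must be excluded by the supply pipeline before
    classification; classifying one is a caller bug, not a data condition.
    """


class IncompleteRecordError(NutriwarnError):
    """A nutrient amount required by an active scope flag is missing."""


class EstimationError(NutriwarnError):
    """A model fit failed (non-convergence, singular covariance)."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace or []


class DegenerateTrendError(NutriwarnError):
    """The pooled proportion is 0 or 1, so no trend test is defined."""


class UndefinedShareError(NutriwarnError):
    """Market share requested for a group/year with zero total sales."""
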