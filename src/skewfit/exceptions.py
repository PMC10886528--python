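"""Exception hierarchy for skewfit.

All skewfit errors derive from :class:`SkewfitError` so callers can catch
package failures with a single except clause while still distinguishing
configuration mistakes from numerical breakdowns.
"""


class SkewfitError(Exception):
    """Base class for all skewfit errors."""


class ConfigurationError(SkewfitError, ValueError):
    """Invalid user-supplied configuration (sample sizes, probabilities, ...)."""


class DomainError(SkewfitError, ValueError):
    """A value lies outside the admissible domain (score range, parameter region)."""


class DataError(SkewfitError, ValueError):
    """The data cannot support the requested operation (too few rows, degenerate)."""


class InferenceError(SkewfitError, ValueError):
    """Not enough information for the requested inference (e.g. too few draws)."""


class NumericalError(SkewfitError, ArithmeticError):
    """A numerical routine failed to converge within its safeguards."""


class ComparisonError(SkewfitError, ValueError):
    """Goodness-of-fit rows are not mutually comparable."""
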