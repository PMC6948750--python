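"""Exception hierarchy.

Every error raised by the library derives from :class:`CorneaMechError`,
split into configuration / data / model branches so callers (and the CLI
exit-code mapping) can distinguish user mistakes from degenerate inputs.
"""


class CorneaMechError(Exception):
    """Base class for all corneamech errors."""


class InvalidGeometryError(CorneaMechError, ValueError):
    """Corneal geometry violates its physical constraints (R > 0, 0 < t < R)."""


class InvalidConstantsError(CorneaMechError, ValueError):
    """Model constants violate their constraints (e.g. applanation area <= 0)."""


class DegenerateModelError(CorneaMechError, ZeroDivisionError):
    """A shell coefficient that must be positive is zero or negative."""


class InvalidInputError(CorneaMechError, ValueError):
    """Malformed numeric input to a statistical or curve operation."""


class UndefinedCorrelationError(InvalidInputError):
    """Pearson correlation requested on a constant (zero-variance) series."""


class DegenerateTestError(InvalidInputError):
    """Paired t-test on differences with zero variance."""


class InsufficientDataError(InvalidInputError):
    """Fewer observations than the statistic requires."""


class ConfigurationError(CorneaMechError):
    """Missing or inconsistent run configuration (column mapping, anchors...)."""


class GenerationError(CorneaMechError):
    """Synthetic-cohort generation could not satisfy its truncation bounds."""
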