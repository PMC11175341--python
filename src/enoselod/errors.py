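"""Exception hierarchy for enoselod.

All package errors derive from :class:`ENoseError` so callers can catch one
base class; each also derives from the closest builtin so generic handling
(``except ValueError``) keeps working.
"""


class ENoseError(Exception):
    """Base class for all enoselod errors."""


class FormatError(ENoseError, ValueError):
    """A file does not conform to the declared CSV dialect or table schema."""


class AnnotationMismatchError(ENoseError, ValueError):
    """Cycle count and annotation count disagree, or ids cannot be joined."""


class MissingPhaseError(ENoseError, KeyError):
    """A required measurement phase is absent from a cycle."""


class ConfigurationError(ENoseError, ValueError):
    """A run configuration is inconsistent with the data (e.g. a day without blanks)."""


class DesignError(ENoseError, ValueError):
    """The calibration design is degenerate (e.g. a single concentration level)."""


class InsufficientBlanksError(ENoseError, ValueError):
    """Fewer blank measurements than the requested statistic needs."""
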