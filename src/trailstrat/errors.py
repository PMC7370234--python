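"""Exception hierarchy for the trailstrat pipeline.

All pipeline errors derive from :class:`TrailstratError` so callers can catch
one base class; subclasses additionally derive from the matching builtin
(``ValueError`` etc.) so generic handling keeps working.
"""


class TrailstratError(Exception):
    """Base class for all trailstrat errors."""


class FormatError(TrailstratError, ValueError):
    """Malformed input table: duplicate ids, empty matrix, missing columns."""


class PanelValueError(TrailstratError, ValueError):
    """Non-numeric, missing or negative cell in an expression matrix."""


class VocabularyError(TrailstratError, ValueError):
    """Response label outside the two-class vocabulary."""


class DomainError(TrailstratError, ValueError):
    """Numeric argument outside its mathematical domain (e.g. fraction > 1)."""


class StructureError(TrailstratError, ValueError):
    """Dose-response grid lacks the monotherapy entries a combination needs."""


class DegenerateError(TrailstratError, ValueError):
    """Degenerate statistical input: zero-variance feature, f_ctrl = 1,
    zero mRNA range, single-class training labels."""


class CoverageError(TrailstratError, KeyError):
    """A sample/cohort does not cover the proteins a fitted model requires."""


class DimensionError(TrailstratError, ValueError):
    """Shape mismatch between arrays that must align."""
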