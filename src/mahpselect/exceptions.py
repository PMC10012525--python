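"""Exception hierarchy for mahpselect.

All library errors derive from :class:`MahpSelectError` so callers can catch
one base class; most also derive from ``ValueError`` because they signal
invalid inputs rather than internal failures.
"""


class MahpSelectError(Exception):
    """Base class for all mahpselect errors."""


class FormatError(MahpSelectError, ValueError):
    """A table is missing required columns or uses an unknown layout."""


class ParseError(MahpSelectError, ValueError):
    """A cell could not be parsed (e.g. non-numeric trait value)."""


class BalanceError(MahpSelectError, ValueError):
    """The design is unbalanced: cells missing or duplicated."""


class DegenerateDataError(MahpSelectError, ValueError):
    """Data carry no usable variation (constant vector, zero column,
    too few families/replicates for the requested decomposition)."""


class UndefinedStatisticError(MahpSelectError, ValueError):
    """A statistic is undefined for these inputs (zero genetic variance,
    constant regressor, zero normal-condition heritability, ...)."""


class AlignmentError(MahpSelectError, ValueError):
    """Two tables that must share labels/ordering do not align."""


class ConfigError(MahpSelectError, ValueError):
    """A pipeline or simulation configuration is inconsistent."""
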