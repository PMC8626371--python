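"""Exception hierarchy.

Every user-facing failure raises a subclass of :class:`SkewcorError` so
callers (and the CLI) can distinguish bad input from genuine bugs.
"""


class SkewcorError(Exception):
    """Base class for all errors raised by skewcor."""


class FormulaParseError(SkewcorError, ValueError):
    """Molecular formula string does not match the element-count grammar."""


class UnknownElementError(SkewcorError, KeyError):
    """Element symbol absent from the isotope table."""


class UnknownResidueError(SkewcorError, KeyError):
    """Amino-acid one-letter code outside the 20 standard residues."""


class UnknownModificationError(SkewcorError, KeyError):
    """Modification name absent from the modification dictionary."""


class InvalidLabelError(SkewcorError, ValueError):
    """Label specification is malformed or incompatible with the formula."""


class MeasurementError(SkewcorError, ValueError):
    """Measurement table fails validation (columns, negative values, NaN)."""


class SimulationError(SkewcorError, ValueError):
    """Simulation specification is invalid."""
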