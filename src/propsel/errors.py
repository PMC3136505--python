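"""Typed exceptions raised by propsel.

Every reader and model-building routine fails with one of these rather than
letting a partially-parsed object escape.
"""


class PropselError(Exception):
    """Base class for all propsel errors."""


class AlignmentShapeError(PropselError):
    """Sequences in an alignment have unequal lengths."""


class FrameError(PropselError):
    """Alignment length is not divisible by 3, or site frames mismatch."""


class AlphabetError(PropselError):
    """Sequence contains characters outside A, C, G, T, N, '-'."""


class TreeParseError(PropselError):
    """Newick string could not be parsed."""


class LabelError(PropselError):
    """Duplicate or mismatched taxon labels."""


class CompletenessError(PropselError):
    """A property table row does not cover all 20 amino acids."""


class PropertyValueError(PropselError):
    """A property table cell is not numeric."""


class PropertyLookupError(PropselError):
    """Requested property or amino acid is absent from the table."""


class DegenerateRangeError(PropselError):
    """A property takes a single value over the neighborhood; no binning exists."""


class DegenerateExpectationError(PropselError):
    """Expected category probability outside (0, 1)."""


class ConfigError(PropselError):
    """Invalid run configuration."""
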