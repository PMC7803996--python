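"""Exception hierarchy shared across the package."""


class RamphyloError(Exception):
    """Base class for all package-specific errors."""


class EmptyInputError(RamphyloError, ValueError):
    """An operation received no usable input (empty gene list, all-zero table, ...)."""


class EmptyResultError(RamphyloError, ValueError):
    """Filtering removed everything; carries the filter report when available."""

    def __init__(self, message, report=None):
        super().__init__(message)
        self.report = report


class TooShortError(RamphyloError, ValueError):
    """A gene has fewer sense codons than the sliding window requires."""


class ConflictError(RamphyloError, ValueError):
    """Two ramp calls disagree for the same (species, ortholog) pair."""


class LabelError(RamphyloError, KeyError):
    """A tree leaf has no corresponding character state / matrix row."""


class NewickParseError(RamphyloError, ValueError):
    """Malformed newick text (unbalanced parentheses, duplicate leaves, ...)."""


class IncomparableTreesError(RamphyloError, ValueError):
    """Two trees share fewer than four leaves and cannot be compared."""


class RequiresRootError(RamphyloError, ValueError):
    """Gain/loss classification needs a rooted tree."""
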