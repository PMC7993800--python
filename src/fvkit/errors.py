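"""Exception hierarchy for fvkit."""


class FvkitError(Exception):
    """Base class for all fvkit errors."""


class RegionError(FvkitError):
    """Unknown or ill-defined structural region."""


class MissingRegionError(FvkitError):
    """A requested region has no residues in the structure."""


class ParseError(FvkitError):
    """Coordinate or summary input could not be parsed."""


class MissingChainError(FvkitError):
    """A chain named in the summary record is absent from the coordinates."""


class ScFvError(FvkitError):
    """Entry is a single-chain Fv (light and heavy under one chain id)."""


class AlignmentInputError(FvkitError):
    """Sequence contains characters outside the 20 standard residues."""


class FilterNotApplicableError(FvkitError):
    """A filter was applied to sequences it cannot compare."""


class ConstraintFitError(FvkitError):
    """Constraint parameter fitting failed (too few or degenerate data)."""


class ConstraintConfigError(FvkitError):
    """Ill-formed constraint configuration (e.g. K > N)."""


class FoldTreeError(FvkitError):
    """Invalid fold-tree construction or manipulation."""


class MetricInputError(FvkitError):
    """Invalid input to a similarity or RMSD metric."""


class FixtureSpecError(FvkitError):
    """Contradictory or unbuildable synthetic-structure specification."""
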