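"""Exception hierarchy.

Everything raised on bad data derives from :class:`PhyloEpiError` so callers
(and the CLI) can distinguish data errors (exit 1) from usage errors (exit 2).
"""


class PhyloEpiError(Exception):
    """Base class for all phyloepi data errors."""


class AlignmentError(PhyloEpiError):
    """Invalid multiple sequence alignment."""


class AlignmentShapeError(AlignmentError):
    """Rows of unequal length, or too few rows/columns."""


class DuplicateLabelError(AlignmentError):
    """Two records share a taxon label, or a label is empty."""


class AlignmentFormatError(AlignmentError):
    """File could not be parsed as an aligned FASTA."""


class AlphabetError(AlignmentError):
    """Sequence contains a character outside {A,C,G,T,N,-}."""


class ConcatenationError(AlignmentError):
    """Blocks to concatenate do not share one label set."""


class ParameterError(PhyloEpiError, ValueError):
    """Invalid analysis or simulation parameter."""


class RecodingError(PhyloEpiError):
    """Sites handed to the recoder are inconsistent with the alignment."""


class DegenerateMatrixError(PhyloEpiError):
    """A recoded character matrix has no columns left."""


class DistanceError(PhyloEpiError):
    """Undefined or invalid pairwise distance."""


class TreeComparisonError(PhyloEpiError):
    """Trees compared over different leaf sets."""
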