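"""Exception hierarchy.

Parse failures, insufficient sampling, and degenerate inputs are distinct
signals so a multi-basin run can tell "bad file" apart from "basin too small".
"""


class CooccurnetError(Exception):
    """Base class for all package errors."""


class ParseError(CooccurnetError):
    """A cell or header in an input table could not be interpreted."""


class InsufficientSamplesError(CooccurnetError):
    """Retained site count fell below the configured minimum for the scale."""


class DegenerateMatrixError(CooccurnetError):
    """Occurrence matrix too small for the requested operation (< 2 species)."""


class DegenerateNetworkError(CooccurnetError):
    """Empty edge list / empty network."""


class CoverageError(CooccurnetError):
    """A partition does not label every node it must cover."""


class AmongGroupsImpossibleError(CooccurnetError):
    """Spatial among-group comparison impossible because k = 1."""


class NoWithinPairsError(CooccurnetError):
    """All groups are singletons: no within-group pair exists."""
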