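"""Exception hierarchy shared across the package."""


class AflPhyloError(Exception):
    """Base class for all package-specific errors."""


class UndefinedDistanceError(AflPhyloError):
    """Raised when a pairwise distance is undefined (e.g. both profiles bandless)."""


class EmptyMatrixError(AflPhyloError):
    """Raised when a filtering/scoring step leaves no loci (or no samples)."""


class InfeasibleGridError(AflPhyloError):
    """Raised when no threshold grid point satisfies the locus-retention floor."""


class NoSignalError(AflPhyloError):
    """Raised when the hybrid-detection step has no delta distribution to test."""


class NumericalDegeneracyError(AflPhyloError):
    """Raised when ascertainment conditioning becomes numerically meaningless."""


class ParseError(AflPhyloError):
    """Raised on malformed input files; carries row/column coordinates when known."""
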