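"""Exception hierarchy for pprsel.

All package-specific errors derive from :class:`PprselError` so callers can
catch everything from this toolkit with one clause.
"""


class PprselError(Exception):
    """Base class for all pprsel errors."""


class FrameError(PprselError):
    """Sequence length is not a multiple of three."""


class StopCodonError(PprselError):
    """An internal in-frame stop codon was found where none is allowed."""

    def __init__(self, taxon: str, codon_index: int, codon: str):
        self.taxon = taxon
        self.codon_index = codon_index
        self.codon = codon
        super().__init__(
            f"internal stop codon {codon} at codon {codon_index} in taxon {taxon!r}"
        )


class AlignmentError(PprselError):
    """Sequences in an alignment are inconsistent (e.g. unequal lengths)."""


class ParseError(PprselError):
    """A file could not be parsed."""


class RangeError(PprselError):
    """A coordinate range falls outside the object it refers to."""


class OverlapError(PprselError):
    """Ranges of one partition overlap."""


class TaxonError(PprselError):
    """Tree and alignment taxa do not match as required."""


class ConvergenceError(PprselError):
    """Numerical optimisation failed to converge from every start."""


class OrderingError(PprselError):
    """A constrained model fit beat the free model beyond numerical noise."""


class EmptyComparisonError(PprselError):
    """No usable codon columns remain in a pairwise comparison."""


class EmptyScanError(PprselError):
    """The alignment is shorter than a single scan window."""


class InsufficientDataError(PprselError):
    """Too few informative codons to attempt a fit."""


class StateError(PprselError):
    """A tree tip is missing an editing state."""


class ReferenceTaxonError(PprselError):
    """The reference taxon itself contains a premature stop codon."""


class ZeroSignalError(PprselError):
    """Both chromatogram peaks are zero; percent editing is undefined."""


class SimulationSpecError(PprselError):
    """A simulation specification is internally inconsistent."""
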