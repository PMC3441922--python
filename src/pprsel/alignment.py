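"""In-frame codon alignments.

Codon columns are numbered 1-based inclusive in every user-facing interface
(files, reports, partition maps); internal arithmetic uses 0-based half-open
slices.  A codon containing ``-`` or ``N`` in a taxon is treated as missing
data for that taxon and column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, FrameError, StopCodonError
from .genetic_code import CODON_INDEX, STOP_CODONS

_VALID_CHARS = frozenset("ACGTN-")


@dataclass
class CodonAlignment:
    """An aligned set of in-frame coding sequences.

    Parameters
    ----------
    taxa : list of str
        Ordered taxon labels, unique.
    sequences : dict
        Taxon -> nucleotide string over ``{A,C,G,T,N,-}``; all the same
        length, divisible by 3.
    allow_stop_codons : bool
        Permit internal in-frame stop codons.  Off by default; switched on
        for truncation analyses, where a premature stop is the signal.
    """

    taxa: list[str]
    sequences: dict[str, str]
    allow_stop_codons: bool = field(default=False, repr=False)

    def __post_init__(self):
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentError("duplicated taxon labels")
        if set(self.taxa) != set(self.sequences):
            raise AlignmentError("taxa and sequence keys differ")
        lengths = {len(self.sequences[t]) for t in self.taxa}
        if len(lengths) > 1:
            raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
        (length,) = lengths or {0}
        if length % 3 != 0:
            raise FrameError(f"alignment length {length} is not divisible by 3")
        self.sequences = {t: s.upper() for t, s in self.sequences.items()}
        for t in self.taxa:
            bad = set(self.sequences[t]) - _VALID_CHARS
            if bad:
                raise AlignmentError(f"invalid characters {sorted(bad)} in taxon {t!r}")
        if not self.allow_stop_codons:
            for t in self.taxa:
                seq = self.sequences[t]
                for k in range(length // 3):
                    codon = seq[3 * k : 3 * k + 3]
                    if codon in STOP_CODONS:
                        raise StopCodonError(t, k + 1, codon)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_codons(self) -> int:
        return len(self.sequences[self.taxa[0]]) // 3 if self.taxa else 0

    def codon(self, taxon: str, k: int) -> str:
        """Codon at 1-based column ``k`` for ``taxon``."""
        s = self.sequences[taxon]
        return s[3 * (k - 1) : 3 * k]

    def codon_codes(self) -> np.ndarray:
        """Integer codon matrix, shape (n_taxa, n_codons).

        Entries index :data:`~pprsel.genetic_code.SENSE_CODONS`; any codon
        containing a gap or ``N`` — or a stop codon, when those are allowed —
        is coded ``-1`` (missing).
        """
        n = self.n_codons
        out = np.full((self.n_taxa, n), -1, dtype=np.int16)
        for r, t in enumerate(self.taxa):
            seq = self.sequences[t]
            for k in range(n):
                out[r, k] = CODON_INDEX.get(seq[3 * k : 3 * k + 3], -1)
        return out

    def select_codons(self, columns: list[int]) -> "CodonAlignment":
        """Sub-alignment of the given 1-based codon columns, in the order given."""
        seqs = {}
        for t in self.taxa:
            s = self.sequences[t]
            seqs[t] = "".join(s[3 * (k - 1) : 3 * k] for k in columns)
        return CodonAlignment(list(self.taxa), seqs, allow_stop_codons=self.allow_stop_codons)

    def slice_codons(self, start: int, end: int) -> "CodonAlignment":
        """Sub-alignment of codons ``start``..``end`` (1-based inclusive)."""
        return self.select_codons(list(range(start, end + 1)))
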