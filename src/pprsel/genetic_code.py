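"""Standard genetic code tables and codon neighbour classification.

The 61 sense codons of the standard nuclear code are indexed in TCAG order
(the conventional ordering in codon-model software).  Precomputed arrays
describing all single-nucleotide codon interchanges — which are transitions,
which are nonsynonymous — back both the Nei–Gojobori site counting and the
Goldman–Yang rate-matrix construction.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

NUCLEOTIDES = "TCAG"

ALL_CODONS = [a + b + c for a in NUCLEOTIDES for b in NUCLEOTIDES for c in NUCLEOTIDES]
STOP_CODONS = frozenset(standard_dna_table.stop_codons)  # TAA, TAG, TGA
SENSE_CODONS = [c for c in ALL_CODONS if c not in STOP_CODONS]
N_SENSE = len(SENSE_CODONS)  # 61

CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
AMINO_ACID = {c: standard_dna_table.forward_table[c] for c in SENSE_CODONS}

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def is_transition(a: str, b: str) -> bool:
    """True if the single-nucleotide change a->b is a transition."""
    return (a in _PURINES and b in _PURINES) or (a in _PYRIMIDINES and b in _PYRIMIDINES)


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def is_sense(codon: str) -> bool:
    return codon in CODON_INDEX


def codon_neighbors(codon: str) -> list[tuple[str, str]]:
    """Classify the 9 single-nucleotide changes of a sense codon.

    Returns a list of (neighbor_codon, label) with label one of
    ``"synonymous"``, ``"nonsynonymous"`` or ``"to-stop"``.

    Raises
    ------
    ValueError
        If ``codon`` is a stop codon or not a valid codon.
    """
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no defined site classification")
    if codon not in CODON_INDEX:
        raise ValueError(f"not a standard-code codon: {codon!r}")
    out = []
    aa = AMINO_ACID[codon]
    for pos in range(3):
        for nuc in NUCLEOTIDES:
            if nuc == codon[pos]:
                continue
            nb = codon[:pos] + nuc + codon[pos + 1 :]
            if nb in STOP_CODONS:
                out.append((nb, "to-stop"))
            elif AMINO_ACID[nb] == aa:
                out.append((nb, "synonymous"))
            else:
                out.append((nb, "nonsynonymous"))
    return out


def minimal_paths(c1: str, c2: str) -> list[list[str]]:
    """All minimal mutational pathways c1 -> c2 avoiding stop codons.

    Each pathway is the list of codons visited, endpoints included.  A
    pathway changes one differing position per step, in some order; orderings
    whose intermediates are stop codons are discarded.
    """
    diff = [p for p in range(3) if c1[p] != c2[p]]
    paths = []
    for order in permutations(diff):
        cur = c1
        path = [cur]
        ok = True
        for pos in order:
            cur = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if cur in STOP_CODONS:
                ok = False
                break
            path.append(cur)
        if ok:
            paths.append(path)
    return paths


def _build_pair_tables():
    """Index arrays over ordered sense-codon pairs one nucleotide apart."""
    ii, jj, ts, nonsyn = [], [], [], []
    for i, ci in enumerate(SENSE_CODONS):
        for pos in range(3):
            for nuc in NUCLEOTIDES:
                if nuc == ci[pos]:
                    continue
                cj = ci[:pos] + nuc + ci[pos + 1 :]
                j = CODON_INDEX.get(cj)
                if j is None:  # stop codon: absorbed, not modelled
                    continue
                ii.append(i)
                jj.append(j)
                ts.append(is_transition(ci[pos], nuc))
                nonsyn.append(AMINO_ACID[ci] != AMINO_ACID[cj])
    return (
        np.asarray(ii, dtype=np.intp),
        np.asarray(jj, dtype=np.intp),
        np.asarray(ts, dtype=bool),
        np.asarray(nonsyn, dtype=bool),
    )


PAIR_I, PAIR_J, PAIR_IS_TRANSITION, PAIR_IS_NONSYN = _build_pair_tables()
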