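"""Nei–Gojobori (1986) counting estimator of dN and dS.

Synonymous and nonsynonymous *sites* are fractional: each of a codon's nine
single-nucleotide neighbours contributes 1/3 of a site to its class, with
changes to stop codons excluded from both classes.  *Differences* between
two codons are averaged over all minimal mutational pathways that avoid stop
codons.  Proportions are corrected for multiple hits with the one-parameter
formula d = -(3/4)·ln(1 - (4/3)p).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .alignment import CodonAlignment
from .errors import EmptyComparisonError
from .genetic_code import AMINO_ACID, CODON_INDEX, codon_neighbors, is_sense, minimal_paths


@dataclass
class SiteCounts:
    """Fractional synonymous / nonsynonymous site counts for one codon."""

    syn_sites: float
    nonsyn_sites: float


@dataclass
class PairwiseEstimate:
    """dN, dS and their ratio for one sequence pair.

    ``omega`` is None when inestimable (dS = 0, no usable divergence, or the
    multiple-hit correction is undefined because p >= 3/4).
    """

    dN: float | None
    dS: float | None
    omega: float | None
    method: str
    n_codons_used: int


def ng86_sites(codon: str) -> SiteCounts:
    """Fractional site counts for a sense codon.

    Raises ``ValueError`` for stop codons.
    """
    syn = nonsyn = 0
    for _, label in codon_neighbors(codon):
        if label == "synonymous":
            syn += 1
        elif label == "nonsynonymous":
            nonsyn += 1
    return SiteCounts(syn_sites=syn / 3.0, nonsyn_sites=nonsyn / 3.0)


def ng86_path_differences(c1: str, c2: str) -> tuple[float, float]:
    """Mean synonymous / nonsynonymous difference counts between two codons.

    Averages over all minimal stop-free mutational pathways.  Returns
    ``(nan, nan)`` when every pathway passes through a stop codon (the
    comparison is then inestimable for this codon pair).
    """
    c1, c2 = c1.upper(), c2.upper()
    for c in (c1, c2):
        if not is_sense(c):
            raise ValueError(f"not a sense codon: {c!r}")
    if c1 == c2:
        return (0.0, 0.0)
    paths = minimal_paths(c1, c2)
    if not paths:
        return (math.nan, math.nan)
    syn_total = nonsyn_total = 0.0
    for path in paths:
        for a, b in zip(path, path[1:]):
            if AMINO_ACID[a] == AMINO_ACID[b]:
                syn_total += 1
            else:
                nonsyn_total += 1
    n = len(paths)
    return (syn_total / n, nonsyn_total / n)


def jukes_cantor_correct(p: float) -> float | None:
    """One-parameter multiple-hit correction; None when p >= 3/4."""
    if p < 0:
        raise ValueError("proportion must be nonnegative")
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


def pairwise_dnds_ng86(s1: str, s2: str) -> PairwiseEstimate:
    """NG86 dN/dS between two equal-length in-frame sequences.

    Codons with missing data (gap or N) in either sequence are dropped
    (pairwise deletion).  Site counts are averaged over the two sequences.
    """
    if len(s1) != len(s2):
        raise ValueError("sequences differ in length")
    if len(s1) % 3:
        raise ValueError("sequence length not divisible by 3")
    s1, s2 = s1.upper(), s2.upper()

    syn_sites = nonsyn_sites = 0.0
    syn_diffs = nonsyn_diffs = 0.0
    n_used = 0
    for k in range(len(s1) // 3):
        c1 = s1[3 * k : 3 * k + 3]
        c2 = s2[3 * k : 3 * k + 3]
        if c1 not in CODON_INDEX or c2 not in CODON_INDEX:
            continue  # missing or stop codon in either sequence
        sd, nd = ng86_path_differences(c1, c2)
        if math.isnan(sd):
            continue  # no stop-free pathway; codon pair inestimable
        sc1, sc2 = ng86_sites(c1), ng86_sites(c2)
        syn_sites += 0.5 * (sc1.syn_sites + sc2.syn_sites)
        nonsyn_sites += 0.5 * (sc1.nonsyn_sites + sc2.nonsyn_sites)
        syn_diffs += sd
        nonsyn_diffs += nd
        n_used += 1

    if n_used == 0:
        raise EmptyComparisonError("no usable codon columns in the comparison")

    pS = syn_diffs / syn_sites if syn_sites > 0 else math.nan
    pN = nonsyn_diffs / nonsyn_sites if nonsyn_sites > 0 else math.nan
    dS = jukes_cantor_correct(pS) if not math.isnan(pS) else None
    dN = jukes_cantor_correct(pN) if not math.isnan(pN) else None
    omega = None
    if dN is not None and dS is not None and dS > 0:
        omega = dN / dS
    return PairwiseEstimate(dN=dN, dS=dS, omega=omega, method="NG86", n_codons_used=n_used)


def pairwise_table_ng86(aln: CodonAlignment):
    """NG86 estimates for every taxon pair of an alignment.

    Returns a list of (taxon1, taxon2, PairwiseEstimate).
    """
    out = []
    for i, t1 in enumerate(aln.taxa):
        for t2 in aln.taxa[i + 1 :]:
            est = pairwise_dnds_ng86(aln.sequences[t1], aln.sequences[t2])
            out.append((t1, t2, est))
    return out
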