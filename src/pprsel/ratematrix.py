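"""Goldman–Yang codon substitution model: rate matrix and P(t).

The instantaneous rate from sense codon i to j is zero unless they differ at
exactly one nucleotide, and otherwise proportional to the target frequency
pi_j, multiplied by kappa for transitions and by omega for nonsynonymous
changes.  The matrix is scaled so the expected number of substitutions per
codon per unit time is one at stationarity; branch lengths are therefore in
expected substitutions per codon.

The model is time-reversible, so Q is diagonalised once per (omega, kappa,
pi) through its symmetrisation  B = diag(sqrt(pi)) Q diag(1/sqrt(pi)),  and
P(t) = exp(Qt) is then a cheap reconstruction for every branch length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import CodonAlignment
from .genetic_code import (
    N_SENSE,
    NUCLEOTIDES,
    PAIR_I,
    PAIR_IS_NONSYN,
    PAIR_IS_TRANSITION,
    PAIR_J,
    SENSE_CODONS,
)

_PI_FLOOR = 1e-6  # avoids zero equilibrium frequencies, which break reversibility


def uniform_frequencies() -> np.ndarray:
    return np.full(N_SENSE, 1.0 / N_SENSE)


def f3x4_frequencies(aln: CodonAlignment) -> np.ndarray:
    """F3x4 codon frequencies from position-specific nucleotide counts.

    Gaps and ambiguous bases are ignored.  Frequencies are floored at a tiny
    positive value and renormalised, so every sense codon stays reachable.
    """
    counts = np.zeros((3, 4))
    nuc_idx = {n: i for i, n in enumerate(NUCLEOTIDES)}
    for t in aln.taxa:
        seq = aln.sequences[t]
        for k in range(aln.n_codons):
            for pos in range(3):
                ch = seq[3 * k + pos]
                if ch in nuc_idx:
                    counts[pos, nuc_idx[ch]] += 1
    if counts.sum() == 0:
        return uniform_frequencies()
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.empty(N_SENSE)
    for i, codon in enumerate(SENSE_CODONS):
        pi[i] = (
            freqs[0, nuc_idx[codon[0]]]
            * freqs[1, nuc_idx[codon[1]]]
            * freqs[2, nuc_idx[codon[2]]]
        )
    pi = np.maximum(pi, _PI_FLOOR)
    return pi / pi.sum()


@dataclass
class CodonModelParams:
    """Parameters of the codon substitution model.

    omega — nonsynonymous/synonymous rate ratio (dN/dS), >= 0
    kappa — transition/transversion rate ratio, > 0
    pi    — equilibrium frequencies over the 61 sense codons
    rate_scaler — global multiplier applied to all branch lengths
    foreground_omega — omega on foreground branches (two-ratio branch
        models); None for single-ratio models
    """

    omega: float
    kappa: float
    pi: np.ndarray = field(default_factory=uniform_frequencies)
    rate_scaler: float = 1.0
    foreground_omega: float | None = None

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.rate_scaler <= 0:
            raise ValueError("rate_scaler must be > 0")
        if self.pi.shape != (N_SENSE,):
            raise ValueError(f"pi must have {N_SENSE} entries")
        if (self.pi < 0).any() or abs(self.pi.sum() - 1.0) > 1e-10:
            raise ValueError("pi must be nonnegative and sum to 1")


def build_rate_matrix(params: CodonModelParams, omega: float | None = None) -> np.ndarray:
    """Normalised instantaneous rate matrix Q for the given parameters.

    ``omega`` overrides ``params.omega`` when given (used for foreground
    branches of two-ratio models).  Rows sum to zero and the mean rate at
    stationarity is one; ``rate_scaler`` is applied to branch lengths, not
    here.
    """
    w = params.omega if omega is None else omega
    if w < 0:
        raise ValueError("omega must be >= 0")
    pi = params.pi
    rates = pi[PAIR_J].copy()
    rates[PAIR_IS_TRANSITION] *= params.kappa
    rates[PAIR_IS_NONSYN] *= w
    Q = np.zeros((N_SENSE, N_SENSE))
    Q[PAIR_I, PAIR_J] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(pi * np.diag(Q)).sum()
    if mu <= 0:
        # omega = 0 with no synonymous route would be fully absorbing; keep
        # Q unscaled (all-zero) rather than divide by zero
        return Q
    return Q / mu


class TransitionOperator:
    """Eigendecomposition of a reversible Q giving fast P(t).

    P(t) = U exp(L t) V with U = diag(pi^-1/2) W, V = W^T diag(pi^1/2) where
    W, L diagonalise the symmetrised matrix.
    """

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        sq = np.sqrt(pi)
        B = Q * (sq[:, None] / sq[None, :])
        B = 0.5 * (B + B.T)  # enforce exact symmetry against roundoff
        self.eigenvalues, W = np.linalg.eigh(B)
        self.U = W / sq[:, None]
        self.V = (W * sq[:, None]).T
        self.pi = pi

    def probability_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to one, entries clipped at zero."""
        if t < 0:
            raise ValueError("branch length must be nonnegative")
        P = (self.U * np.exp(self.eigenvalues * t)) @ self.V
        np.clip(P, 0.0, None, out=P)
        return P


def expected_substitution_fractions(params: CodonModelParams, omega: float | None = None):
    """(rho_syn, rho_nonsyn): flux fractions of Q at stationarity.

    With the normalised Q these sum to one; they split branch lengths into
    expected synonymous and nonsynonymous substitutions per codon.
    """
    Q = build_rate_matrix(params, omega=omega)
    flux = params.pi[PAIR_I] * Q[PAIR_I, PAIR_J]
    total = flux.sum()
    if total <= 0:
        return (0.0, 0.0)
    nonsyn = flux[PAIR_IS_NONSYN].sum() / total
    return (1.0 - nonsyn, nonsyn)


def site_fractions(params: CodonModelParams) -> tuple[float, float]:
    """(S, N): synonymous and nonsynonymous sites per codon (out of 3).

    Physical-site definition: mutational opportunity evaluated at omega = 1
    with the model's kappa and pi.
    """
    rho_s, rho_n = expected_substitution_fractions(params, omega=1.0)
    return (3.0 * rho_s, 3.0 * rho_n)
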