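"""Phylogenetic likelihood of codon alignments by Felsenstein pruning.

Site patterns are compressed once per dataset; conditional likelihoods are
rescaled per pattern at every internal node, so alignments of hundreds of
taxa do not underflow.  Missing codons (gap/N, or stop codons in
truncation-tolerant alignments) enter as uniform partial likelihoods.
"""

from __future__ import annotations

import numpy as np

from .alignment import CodonAlignment
from .errors import TaxonError
from .genetic_code import N_SENSE
from .ratematrix import CodonModelParams, TransitionOperator, build_rate_matrix
from .trees import PhyloTree, TreeIndex


class TreeLikelihood:
    """Pruning engine bound to one alignment/tree pair.

    Rebuilding transition matrices is the only per-evaluation work; the tree
    traversal order, site-pattern compression and tip partials are fixed at
    construction.
    """

    def __init__(self, aln: CodonAlignment, tree: PhyloTree):
        self.index: TreeIndex = tree.index()
        tip_labels = set(self.index.tip_label.values())
        missing = tip_labels - set(aln.taxa)
        if missing:
            raise TaxonError(f"tree taxa absent from alignment: {sorted(missing)}")

        codes = aln.codon_codes()
        row_of = {t: r for r, t in enumerate(aln.taxa)}
        tip_ids = sorted(self.index.tip_label)
        tip_codes = np.stack([codes[row_of[self.index.tip_label[v]]] for v in tip_ids])

        # compress identical codon columns
        patterns, inverse, counts = np.unique(
            tip_codes.T, axis=0, return_inverse=True, return_counts=True
        )
        self.pattern_weights = counts.astype(float)
        self.pattern_inverse = inverse
        self.n_patterns = patterns.shape[0]
        self.n_codons = aln.n_codons

        # fixed tip partial likelihoods: one-hot, or all-ones for missing
        self._tip_partials: dict[int, np.ndarray] = {}
        for r, v in enumerate(tip_ids):
            part = np.zeros((self.n_patterns, N_SENSE))
            col = patterns[:, r]
            obs = col >= 0
            part[np.nonzero(obs)[0], col[obs]] = 1.0
            part[~obs] = 1.0
            self._tip_partials[v] = part

    @property
    def n_informative_codons(self) -> int:
        """Codon columns with at least two resolved taxa."""
        per_pattern = np.zeros(self.n_patterns)
        for part in self._tip_partials.values():
            per_pattern += (part.sum(axis=1) == 1.0).astype(float)
        return int(self.pattern_weights[per_pattern >= 2].sum())

    def loglike(self, params: CodonModelParams) -> float:
        """Log-likelihood under the codon model.

        Branch lengths are the tree's, multiplied by ``params.rate_scaler``;
        edges flagged foreground use ``params.foreground_omega`` when set.
        """
        op_bg = TransitionOperator(build_rate_matrix(params), params.pi)
        op_fg = op_bg
        if params.foreground_omega is not None:
            op_fg = TransitionOperator(
                build_rate_matrix(params, omega=params.foreground_omega), params.pi
            )

        partials: dict[int, np.ndarray] = {}
        logscale: dict[int, np.ndarray] = {}
        zeros = np.zeros(self.n_patterns)
        for v in self.index.postorder:
            kids = self.index.children[v]
            if not kids:
                partials[v] = self._tip_partials[v]
                logscale[v] = zeros
                continue
            acc = np.ones((self.n_patterns, N_SENSE))
            ls = np.zeros(self.n_patterns)
            for child, length, fg in kids:
                op = op_fg if fg else op_bg
                P = op.probability_matrix(length * params.rate_scaler)
                acc *= partials[child] @ P.T
                ls += logscale[child]
                del partials[child], logscale[child]
            smax = acc.max(axis=1)
            if not (smax > 0).all():
                return -np.inf  # some pattern impossible under the model
            acc /= smax[:, None]
            ls += np.log(smax)
            partials[v] = acc
            logscale[v] = ls

        root = self.index.root
        site_like = partials[root] @ params.pi
        if not (site_like > 0).all():
            return -np.inf
        return float(self.pattern_weights @ (np.log(site_like) + logscale[root]))


def tree_log_likelihood(
    aln: CodonAlignment, tree: PhyloTree, params: CodonModelParams
) -> float:
    """Log-likelihood of an alignment on a tree under the codon model."""
    return TreeLikelihood(aln, tree).loglike(params)
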