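"""Rate matrix construction and pruning likelihoods against oracles."""

import numpy as np
import pytest

import pprsel as P
from pprsel.errors import TaxonError
from pprsel.genetic_code import CODON_INDEX, PAIR_I, PAIR_IS_NONSYN, PAIR_J
from pprsel.ratematrix import (
    CodonModelParams,
    TransitionOperator,
    build_rate_matrix,
    f3x4_frequencies,
)


@pytest.fixture(params=[(1.0, 1.0), (0.3, 2.5), (2.0, 8.0)], ids=["neutral", "purifying", "positive"])
def params(request):
    omega, kappa = request.param
    return CodonModelParams(omega=omega, kappa=kappa)


class TestRateMatrix:
    def test_rows_sum_to_zero(self, params):
        Q = build_rate_matrix(params)
        assert np.abs(Q.sum(axis=1)).max() < 1e-10

    def test_stationarity(self, params):
        Q = build_rate_matrix(params)
        assert np.abs(params.pi @ Q).max() < 1e-10

    def test_detailed_balance(self, params):
        Q = build_rate_matrix(params)
        flux = params.pi[:, None] * Q
        assert np.abs(flux - flux.T).max() < 1e-12

    def test_unit_mean_rate(self, params):
        Q = build_rate_matrix(params)
        assert -(params.pi * np.diag(Q)).sum() == pytest.approx(1.0)

    def test_omega_zero_blocks_nonsynonymous_changes(self):
        Q = build_rate_matrix(CodonModelParams(omega=0.0, kappa=2.0))
        assert np.all(Q[PAIR_I[PAIR_IS_NONSYN], PAIR_J[PAIR_IS_NONSYN]] == 0.0)

    def test_multinucleotide_changes_forbidden(self, params):
        Q = build_rate_matrix(params)
        single = np.zeros_like(Q, dtype=bool)
        single[PAIR_I, PAIR_J] = True
        np.fill_diagonal(single, True)
        assert np.all(Q[~single] == 0.0)


class TestTransitionProbabilities:
    def test_p0_is_identity(self, params):
        op = TransitionOperator(build_rate_matrix(params), params.pi)
        assert np.abs(op.probability_matrix(0.0) - np.eye(61)).max() < 1e-8

    def test_rows_sum_to_one(self, params):
        op = TransitionOperator(build_rate_matrix(params), params.pi)
        for t in (0.01, 0.5, 5.0):
            assert np.abs(op.probability_matrix(t).sum(axis=1) - 1).max() < 1e-8

    def test_chapman_kolmogorov(self, params):
        op = TransitionOperator(build_rate_matrix(params), params.pi)
        lhs = op.probability_matrix(0.3) @ op.probability_matrix(0.5)
        assert np.abs(lhs - op.probability_matrix(0.8)).max() < 1e-8


class TestF3x4:
    def test_every_sense_codon_once_gives_positive_pi(self):
        from pprsel.genetic_code import SENSE_CODONS

        aln = P.CodonAlignment(["x"], {"x": "".join(SENSE_CODONS)})
        pi = f3x4_frequencies(aln)
        assert pi.sum() == pytest.approx(1.0)
        assert (pi > 0).all()

    def test_gaps_ignored(self):
        a = P.CodonAlignment(["x", "y"], {"x": "ATGTTT", "y": "---TTT"})
        b = P.CodonAlignment(["x", "y"], {"x": "ATGTTT", "y": "NNNTTT"})
        assert np.allclose(f3x4_frequencies(a), f3x4_frequencies(b))


class TestPruning:
    def test_matches_exhaustive_three_taxa(self, three_taxon_alignment, three_taxon_tree):
        params = CodonModelParams(omega=0.3, kappa=2.5)
        ll = P.tree_log_likelihood(three_taxon_alignment, three_taxon_tree, params)
        op = TransitionOperator(build_rate_matrix(params), params.pi)
        Pa, Pb, Pc = (op.probability_matrix(t) for t in (0.1, 0.25, 0.4))
        codes = three_taxon_alignment.codon_codes()
        oracle = 0.0
        for k in range(codes.shape[1]):
            a, b, c = codes[:, k]
            oracle += np.log(float(params.pi @ (Pa[:, a] * Pb[:, b] * Pc[:, c])))
        assert ll == pytest.approx(oracle, abs=1e-8)

    def test_matches_exhaustive_four_taxa(self, four_taxon_alignment, four_taxon_tree):
        params = CodonModelParams(omega=0.5, kappa=2.0)
        ll = P.tree_log_likelihood(four_taxon_alignment, four_taxon_tree, params)
        op = TransitionOperator(build_rate_matrix(params), params.pi)
        PA, PB, PC, PD, PU, PV = (
            op.probability_matrix(t) for t in (0.1, 0.2, 0.3, 0.05, 0.15, 0.08)
        )
        codes = four_taxon_alignment.codon_codes()
        oracle = 0.0
        for k in range(codes.shape[1]):
            a, b, c, d = codes[:, k]
            Lu = PU @ (PA[:, a] * PB[:, b])  # sum over internal state u
            Lv = PV @ (PC[:, c] * PD[:, d])  # sum over internal state v
            oracle += np.log(float(params.pi @ (Lu * Lv)))
        assert ll == pytest.approx(oracle, abs=1e-8)

    def test_zero_branches_identical_sequences_closed_form(self):
        tree = P.PhyloTree.from_newick("(A:0.0,B:0.0,C:0.0);")
        aln = P.CodonAlignment(["A", "B", "C"], {t: "ATGTTT" for t in "ABC"})
        params = CodonModelParams(omega=0.3, kappa=2.0)
        ll = P.tree_log_likelihood(aln, tree, params)
        expected = np.log(params.pi[CODON_INDEX["ATG"]]) + np.log(params.pi[CODON_INDEX["TTT"]])
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_column_duplication_doubles_loglik(self, three_taxon_tree):
        params = CodonModelParams(omega=0.3, kappa=2.0)
        aln1 = P.CodonAlignment(
            ["A", "B", "C"], {"A": "ATGTTT", "B": "ATGTTC", "C": "ATATTT"}
        )
        aln2 = P.CodonAlignment(
            ["A", "B", "C"], {t: s + s for t, s in aln1.sequences.items()}
        )
        ll1 = P.tree_log_likelihood(aln1, three_taxon_tree, params)
        ll2 = P.tree_log_likelihood(aln2, three_taxon_tree, params)
        assert ll2 == pytest.approx(2 * ll1, abs=1e-10)

    def test_root_invariance(self, four_taxon_alignment, four_taxon_tree):
        params = CodonModelParams(omega=0.4, kappa=3.0)
        ref = P.tree_log_likelihood(four_taxon_alignment, four_taxon_tree, params)
        for leaf in ("A", "C", "D"):
            rr = four_taxon_tree.rerooted_above_leaf(leaf)
            assert P.tree_log_likelihood(four_taxon_alignment, rr, params) == pytest.approx(
                ref, abs=1e-8
            )

    def test_missing_data_marginalized(self, three_taxon_tree):
        # a taxon of all-missing codons contributes nothing: likelihood equals
        # the two-taxon likelihood on the same tree
        params = CodonModelParams(omega=0.3, kappa=2.0)
        aln = P.CodonAlignment(
            ["A", "B", "C"], {"A": "ATGTTT", "B": "ATGTTC", "C": "NNNNNN"}
        )
        ll = P.tree_log_likelihood(aln, three_taxon_tree, params)
        # oracle: drop C by hand
        op = TransitionOperator(build_rate_matrix(params), params.pi)
        Pa, Pb = op.probability_matrix(0.1), op.probability_matrix(0.25)
        codes = aln.codon_codes()
        oracle = 0.0
        for k in range(2):
            a, b = codes[0, k], codes[1, k]
            oracle += np.log(float(params.pi @ (Pa[:, a] * Pb[:, b])))
        assert ll == pytest.approx(oracle, abs=1e-8)

    def test_taxon_mismatch_raises(self, three_taxon_tree):
        aln = P.CodonAlignment(["A", "B"], {"A": "ATGTTT", "B": "ATGTTC"})
        with pytest.raises(TaxonError):
            P.tree_log_likelihood(aln, three_taxon_tree, CodonModelParams(omega=0.3, kappa=2.0))
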