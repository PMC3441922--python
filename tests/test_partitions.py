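"""Partition extraction, per-partition omega tests, helices, truncations."""

import pytest

import pprsel as P
from pprsel.errors import InsufficientDataError, ReferenceTaxonError
from pprsel.partitions import extract_partition


class TestExtraction:
    def test_single_range(self, homogeneous_dataset):
        spec, tree, aln, pmap = homogeneous_dataset
        sub = extract_partition(aln, pmap, "R1_helixA")
        assert sub.n_codons == 12
        assert sub.taxa == aln.taxa

    def test_class_concatenation_in_coordinate_order(self, homogeneous_dataset):
        spec, tree, aln, pmap = homogeneous_dataset
        sub = extract_partition(aln, pmap, "helixA")
        entries = sorted(pmap.by_class("helixA"), key=lambda e: e.start_codon)
        expected_cols = [k for e in entries for k in e.columns()]
        assert sub.n_codons == len(expected_cols)
        t = aln.taxa[0]
        manual = "".join(aln.codon(t, k) for k in expected_cols)
        assert sub.sequences[t] == manual

    def test_partition_completeness(self, homogeneous_dataset):
        """helixA + helixB + coil columns re-sorted give back the gene."""
        spec, tree, aln, pmap = homogeneous_dataset
        cols = []
        for cls in ("helixA", "helixB", "coil"):
            for e in pmap.by_class(cls):
                cols.extend(e.columns())
        assert sorted(cols) == list(range(1, aln.n_codons + 1))

    def test_unknown_selector(self, homogeneous_dataset):
        spec, tree, aln, pmap = homogeneous_dataset
        with pytest.raises(KeyError):
            extract_partition(aln, pmap, "no_such_partition")

    def test_omega_invariant_to_range_order(self, homogeneous_dataset, homogeneous_fit):
        spec, tree, aln, pmap = homogeneous_dataset
        model, gene_fit = homogeneous_fit
        sub = extract_partition(aln, pmap, "helixA")
        cols = list(range(1, sub.n_codons + 1))
        shuffled = sub.select_codons(cols[::-1])
        cfg = P.AnalysisConfig()
        m1 = P.CodonModel(sub, tree, config=cfg, pi=model.pi)
        m2 = P.CodonModel(shuffled, tree, config=cfg, pi=model.pi)
        f1 = m1.fit(fix_kappa=gene_fit.kappa, fix_scaler=gene_fit.rate_scaler)
        f2 = m2.fit(fix_kappa=gene_fit.kappa, fix_scaler=gene_fit.rate_scaler)
        assert f1.omega == pytest.approx(f2.omega, abs=1e-6)


class TestPartitionOmegaTest:
    def test_whole_gene_self_comparison(self, homogeneous_dataset, homogeneous_fit):
        spec, tree, aln, pmap = homogeneous_dataset
        model, gene_fit = homogeneous_fit
        whole = P.PartitionMap([P.PartitionEntry("gene", "other", 1, aln.n_codons)])
        res = P.partition_omega_test(aln, tree, whole, "gene", gene_fit=gene_fit)
        assert res.omega_hat == pytest.approx(gene_fit.omega, abs=1e-3)
        assert res.p_value > 0.9

    def test_insufficient_data(self, homogeneous_dataset, homogeneous_fit):
        spec, tree, aln, pmap = homogeneous_dataset
        model, gene_fit = homogeneous_fit
        tiny = P.PartitionMap([P.PartitionEntry("tiny", "other", 1, 1)])
        with pytest.raises(InsufficientDataError):
            P.partition_omega_test(aln, tree, tiny, "tiny", gene_fit=gene_fit)

    def test_constrained_partition_detected(self):
        """A 30-codon omega=0.02 island inside an omega=0.3 gene is flagged."""
        spec = P.SimulationSpec(
            n_taxa=14,
            n_repeats=1,
            codons_per_helix=30,
            coil_codons=340,
            terminal_domains=(),
            omega_by_class={"helixA": 0.02, "helixB": 0.3, "coil": 0.3},
            total_tree_length=4.0,
            seed=31,
        )
        tree = P.simulate_tree(spec)
        aln, pmap = P.simulate_codon_alignment(tree, spec)
        res = P.partition_omega_test(aln, tree, pmap, "R1_helixA")
        assert res.direction == "below_gene_mean"
        assert res.p_value < 0.05


def test_bh_adjustment_is_monotone(homogeneous_dataset):
    """BH q-values are >= raw p-values and ordered consistently."""
    spec, tree, aln, pmap = homogeneous_dataset
    small = P.PartitionMap(pmap.entries[:4])
    results = P.all_partition_tests(aln, tree, small, adjust="bh")
    for r in results:
        assert r.q_value is not None and r.q_value >= r.p_value - 1e-12
    by_p = sorted(results, key=lambda r: r.p_value)
    qs = [r.q_value for r in by_p]
    assert qs == sorted(qs)


@pytest.fixture(scope="module")
def contrast_data():
    spec = P.SimulationSpec(
            n_taxa=12,
            n_repeats=6,
            codons_per_helix=12,
            coil_codons=11,
            terminal_domains=(),
            omega_by_class={"helixA": 0.05, "helixB": 0.3, "coil": 0.5},
            total_tree_length=4.0,
            seed=90,
    )
    tree = P.simulate_tree(spec)
    aln, pmap = P.simulate_codon_alignment(tree, spec)
    return tree, aln, pmap


class TestHelixComparison:
    def test_contrast_recovered(self, contrast_data):
        tree, aln, pmap = contrast_data
        res = P.helix_comparison_test(aln, tree, pmap)
        assert res.omega_A < res.omega_B
        assert res.p_A_vs_B < 0.05 and res.p_B_vs_A < 0.05

    def test_label_swap_symmetry(self, contrast_data):
        tree, aln, pmap = contrast_data
        swapped = P.PartitionMap(
            [
                P.PartitionEntry(
                    e.name,
                    {"helixA": "helixB", "helixB": "helixA"}.get(
                        e.structural_class, e.structural_class
                    ),
                    e.start_codon,
                    e.end_codon,
                )
                for e in pmap.entries
            ]
        )
        a = P.helix_comparison_test(aln, tree, pmap)
        b = P.helix_comparison_test(aln, tree, swapped)
        assert a.omega_A == pytest.approx(b.omega_B, abs=1e-9)
        assert a.omega_B == pytest.approx(b.omega_A, abs=1e-9)
        assert a.p_A_vs_B == pytest.approx(b.p_B_vs_A, abs=1e-9)


@pytest.fixture(scope="module")
def truncated_dataset():
    spec = P.SimulationSpec(
            n_taxa=8,
            n_repeats=3,
            codons_per_helix=8,
            coil_codons=8,
            terminal_domains=(("E", "E", 10), ("Eplus", "E+", 8), ("DYW", "DYW", 12)),
            omega_by_class={
                "helixA": 0.2,
                "helixB": 0.2,
                "coil": 0.2,
                "E": 0.2,
                "E+": 0.2,
                "DYW": 0.2,
            },
            truncation=("t05", 60),
            total_tree_length=2.0,
            seed=61,
    )
    tree = P.simulate_tree(spec)
    aln, pmap = P.simulate_codon_alignment(tree, spec)
    return aln, pmap


class TestTruncation:
    def test_injected_stop_found(self, truncated_dataset):
        aln, pmap = truncated_dataset
        rep = P.locate_truncation(aln, pmap, "t05", "t01")
        assert rep.first_premature_stop_codon == 60

    def test_downstream_domains_lost(self, truncated_dataset):
        aln, pmap = truncated_dataset
        rep = P.locate_truncation(aln, pmap, "t05", "t01")
        # stop at codon 60: the three C-terminal domains (E from 73) are lost
        assert {"E", "Eplus", "DYW"}.issubset(set(rep.domains_lost))

    def test_intact_taxon_reports_none(self, truncated_dataset):
        aln, pmap = truncated_dataset
        rep = P.locate_truncation(aln, pmap, "t02", "t01")
        assert rep.first_premature_stop_codon is None
        assert rep.domains_lost == []

    def test_stop_in_reference_rejected(self, truncated_dataset):
        aln, pmap = truncated_dataset
        with pytest.raises(ReferenceTaxonError):
            P.locate_truncation(aln, pmap, "t01", "t05")
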