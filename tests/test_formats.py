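"""I/O round-trips, validation errors and coordinate conventions."""

import pandas as pd
import pytest

import pprsel as P
from pprsel.errors import (
    AlignmentError,
    FrameError,
    OverlapError,
    ParseError,
    RangeError,
    StopCodonError,
)


class TestCodonAlignment:
    def test_minimal_valid_fasta(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text(">tx1\nATGTTTAAA\n>tx2\nATGTTCAAG\n")
        aln = P.read_codon_alignment(path)
        assert aln.n_codons == 3
        assert aln.taxa == ["tx1", "tx2"]
        assert aln.codon("tx1", 2) == "TTT"

    def test_length_not_divisible_by_three(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text(">tx1\nATGTTTAAAG\n>tx2\nATGTTCAAGG\n")
        with pytest.raises(FrameError):
            P.read_codon_alignment(path)

    def test_internal_stop_reports_taxon_and_position(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text(">tx1\nATGTAAAAA\n>tx2\nATGTTCAAG\n")
        with pytest.raises(StopCodonError) as exc:
            P.read_codon_alignment(path)
        assert exc.value.taxon == "tx1"
        assert exc.value.codon_index == 2

    def test_stop_allowed_when_requested(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text(">tx1\nATGTAAAAA\n>tx2\nATGTTCAAG\n")
        aln = P.read_codon_alignment(path, allow_stop_codons=True)
        assert aln.codon("tx1", 2) == "TAA"

    def test_unequal_lengths(self):
        with pytest.raises(AlignmentError):
            P.CodonAlignment(["a", "b"], {"a": "ATGTTT", "b": "ATG"})

    def test_roundtrip(self, tmp_path, three_taxon_alignment):
        path = tmp_path / "rt.fasta"
        P.write_codon_alignment(three_taxon_alignment, path)
        back = P.read_codon_alignment(path)
        assert back.taxa == three_taxon_alignment.taxa
        assert back.sequences == three_taxon_alignment.sequences

    @pytest.mark.parametrize("k", [1, 2, 5])
    def test_coordinate_bijection(self, three_taxon_alignment, k):
        # external 1-based codon k <-> internal [k-1, k): selecting column k
        # returns exactly nucleotides 3(k-1)..3k of the original string
        sub = three_taxon_alignment.select_codons([k])
        for t in three_taxon_alignment.taxa:
            s = three_taxon_alignment.sequences[t]
            assert sub.sequences[t] == s[3 * (k - 1) : 3 * k]


class TestTrees:
    def test_newick_with_lengths(self):
        tree = P.PhyloTree.from_newick("((A:0.1,B:0.1):0.05,C:0.2);")
        assert sorted(tree.taxon_labels) == ["A", "B", "C"]
        assert tree.total_length == pytest.approx(0.45)

    def test_missing_lengths_defaulted(self):
        tree = P.PhyloTree.from_newick("((A,B),C);", default_branch_length=0.1)
        assert tree.total_length == pytest.approx(0.4)

    def test_malformed_newick(self):
        with pytest.raises(ParseError):
            P.PhyloTree.from_newick("((A:0.1,B")

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            P.PhyloTree.from_newick("((A:-0.1,B:0.1):0.05,C:0.2);")

    def test_foreground_token_roundtrip(self):
        tree = P.PhyloTree.from_newick("((A#1:0.1,B:0.1):0.05,C:0.2);")
        assert tree.foreground_edge_count() == 1
        assert "A" in tree.taxon_labels and "A#1" not in tree.taxon_labels
        assert "A#1" in tree.to_newick(mark_foreground=True)

    def test_file_roundtrip(self, tmp_path, four_taxon_tree):
        path = tmp_path / "t.nwk"
        four_taxon_tree.write(path)
        back = P.read_tree(path)
        assert sorted(back.taxon_labels) == sorted(four_taxon_tree.taxon_labels)
        assert back.total_length == pytest.approx(four_taxon_tree.total_length)


class TestPartitionMap:
    def test_read_and_validate(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text(
            "name\tclass\tstart_codon\tend_codon\nR1_helixA\thelixA\t5\t16\n"
        )
        aln = P.CodonAlignment(["x"], {"x": "AAA" * 500})
        pmap = P.read_partition_map(path, aln)
        assert pmap.entries[0].n_codons == 12

    def test_range_beyond_alignment(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("name\tclass\tstart_codon\tend_codon\nR1\tP\t400\t501\n")
        aln = P.CodonAlignment(["x"], {"x": "AAA" * 500})
        with pytest.raises(RangeError):
            P.read_partition_map(path, aln)

    def test_overlap_within_one_name(self):
        with pytest.raises(OverlapError):
            P.PartitionMap(
                [
                    P.PartitionEntry("R1_helixA", "helixA", 5, 16),
                    P.PartitionEntry("R1_helixA", "helixA", 10, 20),
                ]
            )

    def test_roundtrip_identical(self, tmp_path):
        pmap = P.PartitionMap(
            [
                P.PartitionEntry("R1_helixA", "helixA", 1, 12),
                P.PartitionEntry("R1_helixB", "helixB", 13, 24),
                P.PartitionEntry("DYW", "DYW", 25, 40),
            ]
        )
        path = tmp_path / "p.tsv"
        P.write_partition_map(pmap, path)
        back = P.read_partition_map(path)
        assert back.to_frame().equals(pmap.to_frame())


class TestEditingStates:
    def test_roundtrip(self, tmp_path):
        table = P.EditingStateTable(
            pd.DataFrame(
                [
                    {"species": "a", "site_id": "s1", "state": "EDITED_C", "percent_edited": "100"},
                    {"species": "b", "site_id": "s1", "state": "GENOMIC_T", "percent_edited": pd.NA},
                    {"species": "c", "site_id": "s1", "state": "UNEDITED_C", "percent_edited": "<10"},
                ]
            )
        )
        path = tmp_path / "st.tsv"
        P.write_editing_states(table, path)
        back = P.read_editing_states(path)
        assert back.states_for("s1") == {"a": "EDITED_C", "b": "GENOMIC_T", "c": "UNEDITED_C"}

    def test_genomic_t_with_percent_rejected(self):
        with pytest.raises(ValueError):
            P.EditingStateTable(
                pd.DataFrame(
                    [{"species": "a", "site_id": "s1", "state": "GENOMIC_T", "percent_edited": "50"}]
                )
            )

    def test_duplicate_rows_rejected(self):
        rows = [{"species": "a", "site_id": "s1", "state": "EDITED_C", "percent_edited": "90"}]
        with pytest.raises(ValueError):
            P.EditingStateTable(pd.DataFrame(rows * 2))


class TestConfig:
    def test_defaults_match_scan_conventions(self):
        cfg = P.AnalysisConfig()
        assert (cfg.window_codons, cfg.step_codons) == (9, 3)

    def test_window_step_ordering_enforced(self):
        with pytest.raises(ValueError):
            P.AnalysisConfig(window_codons=3, step_codons=9)

    def test_yaml_roundtrip(self, tmp_path):
        cfg = P.AnalysisConfig(window_codons=15, step_codons=5, seed=42, frequency_model="uniform")
        path = tmp_path / "cfg.yaml"
        from pprsel.io import write_config

        write_config(cfg, path)
        assert P.read_config(path) == cfg
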