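"""Shared fixtures: tiny hand-built data and moderate simulated datasets."""

import pandas as pd
import pytest

import pprsel as P


@pytest.fixture
def three_taxon_tree():
    return P.PhyloTree.from_newick("(A:0.1,B:0.25,C:0.4);")


@pytest.fixture
def three_taxon_alignment():
    return P.CodonAlignment(
        ["A", "B", "C"],
        {
            "A": "ATGTTTGGACGATCA",
            "B": "ATGTTCGGGCGTTCG",
            "C": "ATATTTGGACGAAGC",
        },
    )


@pytest.fixture
def four_taxon_tree():
    return P.PhyloTree.from_newick("((A:0.1,B:0.2):0.15,(C:0.3,D:0.05):0.08);")


@pytest.fixture
def four_taxon_alignment():
    return P.CodonAlignment(
        ["A", "B", "C", "D"],
        {"A": "ATGTTTGGA", "B": "ATGTTCGGG", "C": "ATATTTGGA", "D": "ATGTTTGGC"},
    )


@pytest.fixture(scope="session")
def homogeneous_dataset():
    """12 taxa, 140 codons, uniform omega = 0.2: one simulated replicate."""
    spec = P.SimulationSpec(
        n_taxa=12,
        n_repeats=4,
        codons_per_helix=12,
        coil_codons=11,
        terminal_domains=(),
        omega_by_class={"helixA": 0.2, "helixB": 0.2, "coil": 0.2},
        total_tree_length=3.0,
        seed=7,
    )
    tree = P.simulate_tree(spec)
    aln, pmap = P.simulate_codon_alignment(tree, spec)
    return spec, tree, aln, pmap


@pytest.fixture(scope="session")
def homogeneous_fit(homogeneous_dataset):
    spec, tree, aln, pmap = homogeneous_dataset
    model = P.CodonModel(aln, tree)
    return model, model.fit()


@pytest.fixture
def eight_tip_tree():
    return P.PhyloTree.from_newick(
        "(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1);"
    )


def make_state_table(states_by_species: dict, site_id: str = "site") -> P.EditingStateTable:
    rows = []
    for sp, state in states_by_species.items():
        rows.append(
            {
                "species": sp,
                "site_id": site_id,
                "state": state,
                "percent_edited": "100" if state == "EDITED_C" else pd.NA,
            }
        )
    return P.EditingStateTable(pd.DataFrame(rows))
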