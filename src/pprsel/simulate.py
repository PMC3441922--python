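"""Synthetic data with known ground truth.

Generates every input the pipeline consumes: Yule trees, codon alignments
evolved under partition-specific omega (the generative twin of the fitted
model), editing-state tables with planted irreversible losses, truncated
sequences, and noisy chromatogram peak heights.  A seed fully determines
every output.

The default gene layout mirrors a PLS-class PPR editing factor: 13 tandem
repeats of 35 codons (12-codon helix A, 12-codon helix B, 11-codon coil)
followed by E, E+ and DYW domains, with helix A under markedly stronger
purifying selection (omega 0.05) than helix B (0.3).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np
from dendropy.simulate import treesim

from .alignment import CodonAlignment
from .errors import SimulationSpecError
from .io import EditingStateTable, PartitionEntry, PartitionMap
from .ratematrix import CodonModelParams, TransitionOperator, build_rate_matrix
from .genetic_code import N_SENSE
from .trees import PhyloTree

import pandas as pd

DEFAULT_OMEGA_BY_CLASS = {
    "helixA": 0.05,
    "helixB": 0.30,
    "coil": 0.50,
    "E": 0.20,
    "E+": 0.20,
    "DYW": 0.08,
    "other": 0.50,
}

DEFAULT_TERMINAL_DOMAINS = (("E", "E", 34), ("Eplus", "E+", 32), ("DYW", "DYW", 100))


@dataclass
class SimulationSpec:
    """Ground-truth description of one synthetic dataset."""

    n_taxa: int = 20
    tree_model: str = "yule"
    total_tree_length: float = 4.0  # expected substitutions per codon, summed
    n_repeats: int = 13
    codons_per_helix: int = 12
    coil_codons: int = 11
    terminal_domains: tuple = DEFAULT_TERMINAL_DOMAINS
    omega_by_class: dict = field(default_factory=lambda: dict(DEFAULT_OMEGA_BY_CLASS))
    kappa: float = 2.0
    pi_model: str = "uniform"
    planted_losses: list = field(default_factory=list)  # (site_id, [branch specs])
    truncation: tuple | None = None  # (taxon, 1-based codon index)
    foreground_omega: float | None = None  # omega on tree branches marked foreground
    seed: int = 0

    def __post_init__(self):
        if any(w < 0 for w in self.omega_by_class.values()):
            raise SimulationSpecError("omega values must be >= 0")
        if self.tree_model not in {"yule", "fixed"}:
            raise SimulationSpecError("tree_model must be 'yule' or 'fixed'")
        if self.pi_model not in {"uniform", "dirichlet"}:
            raise SimulationSpecError("pi_model must be 'uniform' or 'dirichlet'")

    @property
    def n_codons(self) -> int:
        per_repeat = 2 * self.codons_per_helix + self.coil_codons
        return self.n_repeats * per_repeat + sum(d[2] for d in self.terminal_domains)


def simulate_tree(spec: SimulationSpec) -> PhyloTree:
    """A Yule topology with branch lengths rescaled to total_tree_length.

    Leaves are labeled t01, t02, ... in tree order; deterministic given
    ``spec.seed``.
    """
    if spec.n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = random.Random(spec.seed)
    dtree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=spec.n_taxa,
        rng=rng,
    )
    # the simulator stops at the n-th birth, so the youngest cherry has
    # zero-length tips; add the Yule waiting time to the next (uncounted)
    # speciation to every terminal branch
    extra = rng.expovariate(spec.n_taxa)
    for leaf in dtree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    dtree.seed_node.edge.length = None
    width = max(2, len(str(spec.n_taxa)))
    for i, leaf in enumerate(dtree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"t{i:0{width}d}"
    tree = PhyloTree(dtree)
    tree.scale_to_total_length(spec.total_tree_length)
    return tree


def build_partition_map(spec: SimulationSpec) -> PartitionMap:
    """The PartitionMap matching the simulated gene layout."""
    entries = []
    pos = 1
    for r in range(1, spec.n_repeats + 1):
        for suffix, cls, n in (
            ("helixA", "helixA", spec.codons_per_helix),
            ("helixB", "helixB", spec.codons_per_helix),
            ("coil", "coil", spec.coil_codons),
        ):
            if n > 0:
                entries.append(PartitionEntry(f"R{r}_{suffix}", cls, pos, pos + n - 1))
                pos += n
    for name, cls, n in spec.terminal_domains:
        if n > 0:
            entries.append(PartitionEntry(name, cls, pos, pos + n - 1))
            pos += n
    return PartitionMap(entries)


def _equilibrium_frequencies(spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.pi_model == "uniform":
        return np.full(N_SENSE, 1.0 / N_SENSE)
    pi = rng.dirichlet(np.full(N_SENSE, 5.0))
    pi = np.maximum(pi, 1e-6)
    return pi / pi.sum()


def _sample_transitions(P: np.ndarray, parents: np.ndarray, rng: np.random.Generator):
    cum = P.cumsum(axis=1)
    u = rng.random(parents.shape[0])
    child = (cum[parents] < u[:, None]).sum(axis=1)
    return np.minimum(child, N_SENSE - 1)


def simulate_codon_alignment(
    tree: PhyloTree, spec: SimulationSpec
) -> tuple[CodonAlignment, PartitionMap]:
    """Evolve a codon alignment on ``tree`` under partition-specific omega.

    Root codons are drawn from the equilibrium frequencies; each branch
    applies the transition matrix exp(Q_class * t) columnwise with the
    omega of the column's structural class.  Branches marked foreground on
    the tree evolve under ``spec.foreground_omega`` instead (two-ratio
    generative model) when it is set.  The state space is the 61
    sense codons, so no stop codon is ever produced; when ``spec.truncation``
    is set, a TAA stop is then written at the requested codon of the
    requested taxon.
    """
    pmap = build_partition_map(spec)
    n_codons = spec.n_codons
    rng = np.random.default_rng(spec.seed)
    pi = _equilibrium_frequencies(spec, rng)

    class_of = np.empty(n_codons, dtype=object)
    for e in pmap.entries:
        class_of[e.start_codon - 1 : e.end_codon] = e.structural_class
    if any(c is None for c in class_of):
        raise SimulationSpecError("partition map does not cover every codon")

    classes = sorted(set(class_of))
    cols_by_class = {c: np.nonzero(class_of == c)[0] for c in classes}

    def class_operators(omega_override: float | None):
        ops = {}
        for c in classes:
            w = spec.omega_by_class[c] if omega_override is None else omega_override
            params = CodonModelParams(omega=w, kappa=spec.kappa, pi=pi)
            ops[c] = TransitionOperator(build_rate_matrix(params), pi)
        return ops

    operators = class_operators(None)
    fg_operators = operators
    if spec.foreground_omega is not None:
        fg_operators = class_operators(spec.foreground_omega)

    dtree = tree.dendropy_tree
    states: dict[int, np.ndarray] = {}
    root = dtree.seed_node
    states[id(root)] = rng.choice(N_SENSE, size=n_codons, p=pi)
    for node in dtree.preorder_node_iter():
        if node is root:
            continue
        t = float(node.edge.length or 0.0)
        ops = fg_operators if getattr(node.edge, "foreground", False) else operators
        parent_state = states[id(node.parent_node)]
        child_state = parent_state.copy()
        if t > 0:
            for c in classes:
                cols = cols_by_class[c]
                P = ops[c].probability_matrix(t)
                child_state[cols] = _sample_transitions(P, parent_state[cols], rng)
        states[id(node)] = child_state

    from .genetic_code import SENSE_CODONS

    sequences = {}
    taxa = []
    for leaf in dtree.leaf_node_iter():
        label = leaf.taxon.label
        taxa.append(label)
        sequences[label] = "".join(SENSE_CODONS[s] for s in states[id(leaf)])

    allow_stops = False
    if spec.truncation is not None:
        taxon, codon_index = spec.truncation
        if taxon not in sequences:
            raise SimulationSpecError(f"truncation taxon {taxon!r} not in tree")
        if not (1 <= codon_index <= n_codons):
            raise SimulationSpecError(f"truncation codon {codon_index} out of range")
        s = sequences[taxon]
        sequences[taxon] = s[: 3 * (codon_index - 1)] + "TAA" + s[3 * codon_index :]
        allow_stops = True

    return CodonAlignment(taxa, sequences, allow_stop_codons=allow_stops), pmap


def _clade_tips(tree: PhyloTree, branch_spec) -> list[str]:
    """Tips below a branch given as a leaf label or an iterable of labels (MRCA)."""
    if isinstance(branch_spec, str):
        return [branch_spec]
    dtree = tree.dendropy_tree
    node = dtree.mrca(taxa=[tree._find_leaf(lbl).taxon for lbl in branch_spec])
    return [leaf.taxon.label for leaf in node.leaf_iter()]


def simulate_editing_states(
    tree: PhyloTree, planted_losses, seed: int
) -> EditingStateTable:
    """Tip editing states with losses planted on chosen branches.

    ``planted_losses`` is a list of (site_id, [branch specs]); every tip
    below a planted branch lacks editing at that site — the mechanism
    (GENOMIC_T or UNEDITED_C) is drawn per clade — and all other tips are
    EDITED_C at 100%.  Branches of one site must be non-nested.
    """
    rng = np.random.default_rng(seed)
    tips = tree.taxon_labels
    sites: dict[str, list[list[str]]] = {}
    for site_id, branch_specs in planted_losses:
        clades = [_clade_tips(tree, b) for b in branch_specs]
        for i, a in enumerate(clades):
            for b in clades[i + 1 :]:
                if set(a) & set(b):
                    raise SimulationSpecError(
                        f"planted loss branches for {site_id!r} are nested or overlap"
                    )
        sites.setdefault(site_id, []).extend(clades)

    rows = []
    for site_id, clades in sites.items():
        lost_state: dict[str, str] = {}
        for clade in clades:
            mechanism = "GENOMIC_T" if rng.random() < 0.5 else "UNEDITED_C"
            for t in clade:
                lost_state[t] = mechanism
        for t in tips:
            state = lost_state.get(t, "EDITED_C")
            rows.append(
                {
                    "species": t,
                    "site_id": site_id,
                    "state": state,
                    "percent_edited": {
                        "EDITED_C": "100",
                        "UNEDITED_C": "<10",
                        "GENOMIC_T": pd.NA,
                    }[state],
                }
            )
    return EditingStateTable(pd.DataFrame(rows))


def simulate_peak_heights(
    true_fraction: float, noise_sd: float, n: int, seed: int
) -> pd.DataFrame:
    """Noisy (peak_C, peak_T) pairs for a true edited fraction.

    Peak heights are 100*(1-f) and 100*f distorted by multiplicative
    Gaussian noise, truncated at zero.
    """
    if not 0.0 <= true_fraction <= 1.0:
        raise ValueError("true_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    base_c = 100.0 * (1.0 - true_fraction)
    base_t = 100.0 * true_fraction
    peak_c = np.maximum(0.0, base_c * (1.0 + rng.normal(0.0, noise_sd, size=n)))
    peak_t = np.maximum(0.0, base_t * (1.0 + rng.normal(0.0, noise_sd, size=n)))
    return pd.DataFrame(
        {
            "sample": [f"s{i + 1:03d}" for i in range(n)],
            "peak_C": peak_c,
            "peak_T": peak_t,
        }
    )
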