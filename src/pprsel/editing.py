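"""C-to-U RNA-editing sites: quantification and loss parsimony.

Percent editing is the %T signal at the edited position of a bulk-sequencing
chromatogram, rounded to the nearest 10% with values under 10% reported as a
below-threshold flag.  Editing-site losses are counted under a Dollo model:
editing is ancestrally present (single gain) and can only be lost, so the
minimum number of independent losses is the number of maximal clades whose
tips all lack editing — whether by genomic C-to-T substitution (GENOMIC_T)
or by silencing of conversion (UNEDITED_C).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import RangeError, StateError, ZeroSignalError
from .io import BELOW_10, EditingStateTable
from .trees import PhyloTree

LOSS_STATES = {"GENOMIC_T", "UNEDITED_C"}


@dataclass
class EditingCall:
    peak_C: float
    peak_T: float
    percent_T_raw: float
    percent_T_rounded: int | str  # multiple of 10, or the "<10" flag


@dataclass
class CisElement:
    """The 26-nt neighbourhood -20..+5 around an edited C."""

    site_id: str
    sequence: str
    edited_position_offset: int = 21  # 1-based within the window


@dataclass
class LossClade:
    tips: list[str]
    mechanism: str  # GENOMIC_T | UNEDITED_C | MIXED


@dataclass
class LossParsimonyResult:
    site_id: str
    min_losses: int
    loss_clades: list[LossClade]

    @property
    def mechanisms(self) -> list[str]:
        return [c.mechanism for c in self.loss_clades]


def percent_edited(peak_C: float, peak_T: float) -> EditingCall:
    """Percent editing from chromatogram peak heights.

    raw %T = 100 * T / (C + T); rounded to the nearest multiple of 10 with
    ties rounding up; raw values below 10 are flagged "<10" rather than
    rounded.
    """
    if peak_C < 0 or peak_T < 0:
        raise ValueError("peak heights must be nonnegative")
    total = peak_C + peak_T
    if total == 0:
        raise ZeroSignalError("both peaks are zero; percent editing undefined")
    raw = 100.0 * peak_T / total
    if raw < 10.0:
        rounded: int | str = BELOW_10
    else:
        rounded = int((raw + 5.0) // 10.0) * 10  # ties round up
    return EditingCall(peak_C=peak_C, peak_T=peak_T, percent_T_raw=raw, percent_T_rounded=rounded)


def classify_site(states: EditingStateTable, site_id: str) -> str:
    """"homogeneous" when every species edits the site, else "heterogeneous".

    Requires calls from at least two species.
    """
    site_states = states.states_for(site_id)
    if len(site_states) < 2:
        raise ValueError(f"site {site_id!r} has calls for fewer than 2 species")
    return "homogeneous" if all(s == "EDITED_C" for s in site_states.values()) else "heterogeneous"


def count_min_losses(
    tree: PhyloTree, states: EditingStateTable, site_id: str
) -> LossParsimonyResult:
    """Minimum number of independent editing losses on the tree (Dollo).

    Every maximal subtree whose tips all lack editing is one loss event; its
    mechanism is GENOMIC_T or UNEDITED_C when uniform across the clade,
    MIXED otherwise.  A loss happens on a branch, so the root itself can
    never be a loss clade: in the degenerate case where no tip retains
    editing, each child subtree of the root counts as one loss.
    """
    state_of = states.states_for(site_id)
    dtree = tree.dendropy_tree
    tips = [leaf.taxon.label for leaf in dtree.leaf_node_iter()]
    missing = [t for t in tips if t not in state_of]
    if missing:
        raise StateError(f"no state at {site_id!r} for tips: {missing}")

    all_lost: dict[int, bool] = {}
    clade_tips: dict[int, list[str]] = {}
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            all_lost[id(node)] = state_of[label] in LOSS_STATES
            clade_tips[id(node)] = [label]
        else:
            kids = node.child_nodes()
            all_lost[id(node)] = all(all_lost[id(c)] for c in kids)
            clade_tips[id(node)] = [t for c in kids for t in clade_tips[id(c)]]

    root = dtree.seed_node
    clades: list[LossClade] = []
    for node in dtree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        if all_lost[id(node)] and (parent is root or not all_lost[id(parent)]):
            tips_here = clade_tips[id(node)]
            mech = {state_of[t] for t in tips_here}
            clades.append(
                LossClade(
                    tips=tips_here,
                    mechanism=mech.pop() if len(mech) == 1 else "MIXED",
                )
            )
    return LossParsimonyResult(site_id=site_id, min_losses=len(clades), loss_clades=clades)


def annotate_loss_branches(tree: PhyloTree, result: LossParsimonyResult) -> str:
    """Newick string with '*LOSS*' appended to the label of each loss clade's stem node."""
    clone = tree.copy()
    dtree = clone.dendropy_tree
    for clade in result.loss_clades:
        if len(clade.tips) == 1:
            node = clone._find_leaf(clade.tips[0])
        else:
            node = dtree.mrca(taxa=[clone._find_leaf(t).taxon for t in clade.tips])
        if node.taxon is not None:
            node.taxon.label = node.taxon.label + "*LOSS*"
        else:
            node.label = (node.label or "") + "*LOSS*"
    return dtree.as_string(schema="newick", suppress_rooting=True).strip()


def extract_cis_element(seq: str, edit_pos: int, site_id: str = "") -> CisElement:
    """The 26-nt window -20..+5 around the edited position (1-based).

    Requires 20 nucleotides upstream and 5 downstream of ``edit_pos``.
    """
    seq = seq.upper()
    if edit_pos < 21 or edit_pos + 5 > len(seq):
        raise RangeError(
            f"cis-element window -20..+5 around position {edit_pos} exceeds the sequence"
        )
    window = seq[edit_pos - 21 : edit_pos + 5]
    if window[20] not in {"C", "T"}:
        raise ValueError(f"edited position holds {window[20]!r}; expected C or T")
    return CisElement(site_id=site_id, sequence=window)
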