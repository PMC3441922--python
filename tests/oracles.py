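"""Independent brute-force oracles used by the test suite.

Everything here is implemented from first principles — Biopython
translation, exhaustive enumeration — and never calls the code paths it
checks.
"""

from itertools import permutations, product

import numpy as np
from Bio.Seq import Seq

NUCS = "TCAG"
STOPS = {"TAA", "TAG", "TGA"}


def translate(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_site_counts(codon: str):
    """(syn_sites, nonsyn_sites) by direct enumeration of the 9 neighbours."""
    syn = nonsyn = 0
    aa = translate(codon)
    for pos, nuc in product(range(3), NUCS):
        if nuc == codon[pos]:
            continue
        nb = codon[:pos] + nuc + codon[pos + 1 :]
        if nb in STOPS:
            continue
        if translate(nb) == aa:
            syn += 1
        else:
            nonsyn += 1
    return syn / 3.0, nonsyn / 3.0


def oracle_path_differences(c1: str, c2: str):
    """(syn, nonsyn) mean step counts over stop-free minimal pathways."""
    diff = [p for p in range(3) if c1[p] != c2[p]]
    per_path = []
    for order in permutations(diff):
        cur, syn, nonsyn, ok = c1, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOPS:
                ok = False
                break
            if translate(cur) == translate(nxt):
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if ok:
            per_path.append((syn, nonsyn))
    if not per_path:
        return None
    return (
        sum(s for s, _ in per_path) / len(per_path),
        sum(n for _, n in per_path) / len(per_path),
    )


def oracle_dollo_min_losses(children: dict, root, lost_tips: set, tips: set) -> int:
    """Minimum loss-only events by enumeration over ancestral labelings.

    ``children`` maps node -> list of child nodes (tips have no entry).
    The root is ancestrally edited (state 1); an edge may switch 1 -> 0
    (one loss) but never 0 -> 1.  Returns the minimum number of loss edges
    over all consistent internal labelings.
    """
    internal = [n for n in children if n != root]
    best = None
    for bits in product([0, 1], repeat=len(internal)):
        label = dict(zip(internal, bits))
        label[root] = 1
        for t in tips:
            label[t] = 0 if t in lost_tips else 1

        def ok_and_count(node):
            total = 0
            for ch in children.get(node, []):
                if label[node] == 0 and label[ch] == 1:
                    return None  # regain: forbidden
                if label[node] == 1 and label[ch] == 0:
                    total += 1
                sub = ok_and_count(ch)
                if sub is None:
                    return None
                total += sub
            return total

        count = ok_and_count(root)
        if count is not None and (best is None or count < best):
            best = count
    return best


def dendropy_children_map(tree):
    """(children, root, tips) adjacency for oracle_dollo_min_losses."""
    dtree = tree.dendropy_tree
    children = {}
    tips = set()
    for node in dtree.preorder_node_iter():
        if node.is_leaf():
            tips.add(node.taxon.label)
        else:
            key = id(node)
            children[key] = [
                c.taxon.label if c.is_leaf() else id(c) for c in node.child_nodes()
            ]
    return children, id(dtree.seed_node), tips
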