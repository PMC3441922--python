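"""Phylogenies: a thin wrapper over dendropy trees.

Branch lengths are in expected substitutions per codon.  Foreground branches
for two-ratio branch models are marked in Newick with the suffix token
``#1`` on the branch's child node (the convention used by codon-model
software); the wrapper strips the token and records the flag on the edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy

from .errors import ParseError

logger = logging.getLogger(__name__)

_FOREGROUND_SUFFIX = "#1"


@dataclass
class TreeIndex:
    """Flat postorder arrays for likelihood computation.

    Nodes are numbered 0..n_nodes-1; ``children[v]`` lists
    ``(child_id, branch_length, is_foreground)``; leaves have empty child
    lists and an entry in ``tip_label``.
    """

    n_nodes: int
    root: int
    postorder: list[int]  # all nodes, children before parents
    children: list[list[tuple[int, float, bool]]]
    tip_label: dict[int, str]

    @property
    def tip_labels(self) -> list[str]:
        return [self.tip_label[v] for v in self.postorder if v in self.tip_label]


class PhyloTree:
    """A rooted or unrooted phylogeny with branch lengths.

    Thin wrapper around :class:`dendropy.Tree` adding validation, foreground
    branch markers and the flat index used by the pruning engine.
    """

    def __init__(self, dtree: dendropy.Tree):
        self._tree = dtree

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str, default_branch_length: float | None = None) -> "PhyloTree":
        """Parse a Newick string.

        Missing branch lengths are replaced by ``default_branch_length``
        (with a logged warning) when given, else by 0.0.  Negative branch
        lengths raise ``ValueError``; malformed Newick raises ``ParseError``.
        """
        try:
            dtree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise ParseError(f"could not parse Newick: {exc}") from exc
        tree = cls(dtree)
        tree._strip_foreground_tokens()
        tree._fill_branch_lengths(default_branch_length)
        tree._validate()
        return tree

    @classmethod
    def from_file(cls, path, default_branch_length: float | None = None) -> "PhyloTree":
        with open(path) as fh:
            return cls.from_newick(fh.read(), default_branch_length)

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1))

    # -- internals ----------------------------------------------------

    def _strip_foreground_tokens(self):
        for node in self._tree:
            label = node.taxon.label if node.taxon is not None else node.label
            if label and label.endswith(_FOREGROUND_SUFFIX):
                stripped = label[: -len(_FOREGROUND_SUFFIX)]
                if node.taxon is not None:
                    node.taxon.label = stripped
                else:
                    node.label = stripped or None
                node.edge.foreground = True
            elif not hasattr(node.edge, "foreground"):
                node.edge.foreground = False

    def _fill_branch_lengths(self, default: float | None):
        filled = 0
        for edge in self._tree.preorder_edge_iter():
            if edge.head_node is self._tree.seed_node:
                continue
            if edge.length is None:
                edge.length = default if default is not None else 0.0
                filled += 1
        if filled and default is not None:
            logger.warning("set %d missing branch lengths to default %.4g", filled, default)

    def _validate(self):
        for edge in self._tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError(f"negative branch length {edge.length}")
        labels = self.taxon_labels
        if len(set(labels)) != len(labels):
            raise ParseError("duplicated leaf labels in tree")

    # -- properties ---------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def taxon_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    @property
    def total_length(self) -> float:
        return sum(
            e.length or 0.0
            for e in self._tree.preorder_edge_iter()
            if e.head_node is not self._tree.seed_node
        )

    def scale_to_total_length(self, total: float) -> None:
        """Rescale all branch lengths so they sum to ``total`` (in place)."""
        cur = self.total_length
        if cur <= 0:
            raise ValueError("tree has zero total length; cannot rescale")
        f = total / cur
        for e in self._tree.preorder_edge_iter():
            if e.length is not None:
                e.length *= f

    # -- foreground marking -------------------------------------------

    def mark_foreground(self, spec) -> None:
        """Mark branches as foreground for two-ratio branch models.

        ``spec`` is a leaf label (marks its terminal branch), an iterable of
        leaf labels (marks the stem branch of their MRCA), or ``"all"``.
        """
        if spec == "all":
            for e in self._tree.preorder_edge_iter():
                e.foreground = True
            return
        if isinstance(spec, str):
            node = self._find_leaf(spec)
        else:
            taxa = [self._find_leaf(lbl).taxon for lbl in spec]
            node = self._tree.mrca(taxa=taxa)
        node.edge.foreground = True

    def foreground_edge_count(self) -> int:
        return sum(
            1
            for e in self._tree.preorder_edge_iter()
            if getattr(e, "foreground", False) and e.head_node is not self._tree.seed_node
        )

    def _find_leaf(self, label: str):
        for leaf in self._tree.leaf_node_iter():
            if leaf.taxon.label == label:
                return leaf
        raise KeyError(f"no leaf labeled {label!r}")

    # -- serialization ------------------------------------------------

    def to_newick(self, mark_foreground: bool = True) -> str:
        tree = self._tree.clone(depth=1)
        if mark_foreground:
            for node in tree:
                if getattr(node.edge, "foreground", False):
                    if node.taxon is not None:
                        node.taxon.label = node.taxon.label + _FOREGROUND_SUFFIX
                    else:
                        node.label = (node.label or "") + _FOREGROUND_SUFFIX
        s = tree.as_string(schema="newick", suppress_rooting=True, unquoted_underscores=True)
        return s.strip()

    def write(self, path, mark_foreground: bool = True) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick(mark_foreground) + "\n")

    # -- rerooting (used for likelihood invariance checks) -------------

    def rerooted_above_leaf(self, label: str) -> "PhyloTree":
        """A copy rerooted on the terminal branch of ``label``, split halfway."""
        clone = self.copy()
        leaf = clone._find_leaf(label)
        length = leaf.edge.length or 0.0
        clone._tree.reroot_at_edge(leaf.edge, length1=length / 2, length2=length / 2)
        return clone

    # -- flattening ----------------------------------------------------

    def index(self) -> TreeIndex:
        """Flatten to postorder arrays for the pruning engine."""
        ids: dict[int, int] = {}
        postorder: list[int] = []
        children: list[list[tuple[int, float, bool]]] = []
        tip_label: dict[int, str] = {}
        for node in self._tree.postorder_node_iter():
            vid = len(postorder)
            ids[id(node)] = vid
            postorder.append(vid)
            kids = []
            for ch in node.child_nodes():
                kids.append(
                    (
                        ids[id(ch)],
                        float(ch.edge.length or 0.0),
                        bool(getattr(ch.edge, "foreground", False)),
                    )
                )
            children.append(kids)
            if node.is_leaf():
                tip_label[vid] = node.taxon.label
        root = ids[id(self._tree.seed_node)]
        return TreeIndex(
            n_nodes=len(postorder),
            root=root,
            postorder=postorder,
            children=children,
            tip_label=tip_label,
        )


def read_tree(path, default_branch_length: float | None = None) -> PhyloTree:
    """Read a Newick tree file; see :meth:`PhyloTree.from_newick`."""
    return PhyloTree.from_file(path, default_branch_length=default_branch_length)
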