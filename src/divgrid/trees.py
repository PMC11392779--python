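"""Rooted trees and the shared branch-length engine.

One tree class serves two roles: the dated phylogeny (branch lengths in time
units) and the functional dendrogram produced by UPGMA on trait
dissimilarities (branch lengths in dissimilarity units).  All per-cell
diversity metrics reduce to sums over branches of the subtree spanning the
species present in a cell:

* branch-sum diversity (Faith-style PD, or FD on the dendrogram): the sum of
  the spanning subtree's branch lengths, either rooted at the leaf set's MRCA
  (``mode="mrca"``) or including the MRCA-to-root path (``mode="root"``);
* range-weighted endemism (PE, or FE on the dendrogram): the same sum with
  each branch length L_b divided by the branch's range |r_b|, the number of
  grid cells in which at least one descendant of the branch occurs.

Newick reading is delegated to dendropy; validation (unique leaf labels,
branch lengths present) and writing are handled here so round-trips are
lossless to printed precision.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterator

import dendropy
import numpy as np

from .errors import LookupLabelError, TreeParseError

__all__ = [
    "TreeNode",
    "RootedTree",
    "read_newick",
    "write_newick",
    "graft_missing_species",
    "branch_sum_diversity",
    "BranchTable",
    "range_weighted_endemism",
]


@dataclass
class TreeNode:
    """A node of a rooted tree; ``length`` is the edge to the parent."""

    label: str | None = None
    length: float | None = None
    children: list["TreeNode"] = field(default_factory=list)
    parent: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child


class RootedTree:
    """A rooted tree with branch lengths and uniquely labelled leaves."""

    def __init__(self, root: TreeNode):
        self.root = root
        self._validate()

    # -- construction / IO -------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "RootedTree":
        return read_newick(text)

    def to_newick(self) -> str:
        return write_newick(self)

    # -- traversal ---------------------------------------------------------

    def postorder(self) -> Iterator[TreeNode]:
        stack: list[tuple[TreeNode, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for child in reversed(node.children):
                stack.append(child)

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    @property
    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    # -- derived quantities ------------------------------------------------

    @property
    def total_length(self) -> float:
        return float(
            sum(n.length for n in self.postorder() if n.parent is not None)
        )

    def node_depths(self) -> dict[int, float]:
        """Depth (distance from root) keyed by ``id(node)``."""
        depths: dict[int, float] = {id(self.root): 0.0}
        for node in self.preorder():
            if node.parent is not None:
                depths[id(node)] = depths[id(node.parent)] + node.length
        return depths

    def leaf_depths(self) -> dict[str, float]:
        depths = self.node_depths()
        return {n.label: depths[id(n)] for n in self.leaves()}

    def is_ultrametric(self, rel_tol: float = 1e-9) -> bool:
        depths = np.array(list(self.leaf_depths().values()))
        spread = depths.max() - depths.min()
        scale = max(depths.max(), 1e-300)
        return bool(spread < rel_tol * scale or spread == 0.0)

    def mrca(self, labels: set[str]) -> TreeNode:
        """Most recent common ancestor of a set of leaf labels."""
        by_label = {n.label: n for n in self.leaves()}
        missing = sorted(labels - by_label.keys())
        if missing:
            raise LookupLabelError(f"labels not in tree: {missing}")
        nodes = [by_label[lbl] for lbl in labels]
        ancestors: set[int] = set()
        node = nodes[0]
        while node is not None:
            ancestors.add(id(node))
            node = node.parent
        deepest = nodes[0]
        for other in nodes[1:]:
            node = other
            while id(node) not in ancestors:
                node = node.parent
            # restrict the candidate ancestor chain to this node upward
            chain = set()
            probe: TreeNode | None = node
            while probe is not None:
                chain.add(id(probe))
                probe = probe.parent
            ancestors &= chain
        node = nodes[0]
        while id(node) not in ancestors:
            node = node.parent
        return node

    # -- copying -----------------------------------------------------------

    def copy(self) -> "RootedTree":
        def clone(node: TreeNode) -> TreeNode:
            new = TreeNode(label=node.label, length=node.length)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return RootedTree(clone(self.root))

    # -- validation --------------------------------------------------------

    def _validate(self) -> None:
        labels = [n.label for n in self.postorder() if n.is_leaf]
        if any(lbl is None for lbl in labels):
            raise TreeParseError("unlabelled leaf")
        dupes = sorted({lbl for lbl in labels if labels.count(lbl) > 1})
        if dupes:
            raise TreeParseError(f"duplicate leaf labels: {dupes}")
        for node in self.postorder():
            if node.parent is not None:
                if node.length is None:
                    raise TreeParseError(
                        f"missing branch length above {node.label or 'internal node'}"
                    )
                if node.length < 0:
                    raise TreeParseError(
                        f"negative branch length above {node.label or 'internal node'}"
                    )


def read_newick(text: str) -> RootedTree:
    """Parse a newick string into a :class:`RootedTree`.

    Raises :class:`TreeParseError` naming the offending token on malformed
    input, duplicate leaf labels, or missing branch lengths.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several token-level errors
        raise TreeParseError(f"newick parse failed: {exc}") from exc

    def convert(dnode: dendropy.Node) -> TreeNode:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label is not None:
            label = dnode.label
        node = TreeNode(label=label if not dnode.child_nodes() else None,
                        length=dnode.edge.length)
        for dchild in dnode.child_nodes():
            node.add_child(convert(dchild))
        return node

    root = convert(dtree.seed_node)
    root.length = None  # root edge length carries no information here
    return RootedTree(root)


def write_newick(tree: RootedTree, precision: int = 12) -> str:
    """Serialize a tree to newick, lossless to printed precision."""

    def fmt(x: float) -> str:
        s = f"{x:.{precision}g}"
        return s

    buf = io.StringIO()

    def emit(node: TreeNode) -> None:
        if node.children:
            buf.write("(")
            for i, child in enumerate(node.children):
                if i:
                    buf.write(",")
                emit(child)
            buf.write(")")
        if node.label is not None:
            buf.write(node.label)
        if node.parent is not None:
            buf.write(f":{fmt(node.length)}")

    emit(tree.root)
    buf.write(";")
    return buf.getvalue()


# ---------------------------------------------------------------------------
# grafting of species absent from the tree


def graft_missing_species(
    tree: RootedTree,
    species_to_genus: dict[str, str],
    genus_of_leaf: dict[str, str],
) -> tuple[RootedTree, list[dict]]:
    """Attach species without a tip to their genus, genus-level placement.

    Species whose genus has two or more leaves attach as a new child of the
    genus MRCA, with pendant length equal to the mean depth of the MRCA's
    existing leaves below it (creating a polytomy).  Species whose genus has
    exactly one leaf attach at the midpoint of that leaf's pendant branch.
    Species whose genus is absent from the tree are dropped and logged.
    Ultrametric input stays ultrametric.

    Returns the augmented tree (a copy) and a log of dicts with keys
    ``species``, ``action`` and ``attachment_depth``.
    """
    out = tree.copy()
    log: list[dict] = []
    for species in sorted(species_to_genus):
        genus = species_to_genus[species]
        leaves = [n for n in out.leaves() if genus_of_leaf.get(n.label) == genus]
        if not leaves:
            log.append({"species": species, "action": "dropped_no_genus",
                        "attachment_depth": np.nan})
            continue
        depths = out.node_depths()
        if len(leaves) == 1:
            leaf = leaves[0]
            pendant = leaf.length
            parent = leaf.parent
            split = TreeNode(length=pendant / 2.0)
            idx = parent.children.index(leaf)
            parent.children[idx] = split
            split.parent = parent
            leaf.length = pendant / 2.0
            split.add_child(leaf)
            split.add_child(TreeNode(label=species, length=pendant / 2.0))
            attach_depth = depths[id(parent)] + pendant / 2.0
            action = "midpoint_single_leaf"
        else:
            mrca = out.mrca({n.label for n in leaves})
            below = [
                n for n in out.leaves()
                if _has_ancestor(n, mrca)
            ]
            pendant = float(np.mean([depths[id(n)] - depths[id(mrca)]
                                     for n in below]))
            mrca.add_child(TreeNode(label=species, length=pendant))
            attach_depth = depths[id(mrca)]
            action = "polytomy_genus_mrca"
        log.append({"species": species, "action": action,
                    "attachment_depth": attach_depth})
        genus_of_leaf = dict(genus_of_leaf)
        genus_of_leaf[species] = genus
    return RootedTree(out.root), log


def _has_ancestor(node: TreeNode, ancestor: TreeNode) -> bool:
    probe: TreeNode | None = node
    while probe is not None:
        if probe is ancestor:
            return True
        probe = probe.parent
    return False


# ---------------------------------------------------------------------------
# branch-sum diversity and range-weighted endemism


def branch_sum_diversity(
    tree: RootedTree, leafset: set[str] | list[str], mode: str = "root"
) -> float:
    """Sum of branch lengths of the subtree spanning ``leafset``.

    ``mode="mrca"`` sums the branches of the minimal spanning subtree rooted
    at the leaf set's MRCA (a singleton leaf set gives 0); ``mode="root"``
    additionally includes the MRCA-to-root path.
    """
    _check_mode(mode)
    leafset = set(leafset)
    if not leafset:
        raise ValueError("leafset must be non-empty")
    by_label = {n.label: n for n in tree.leaves()}
    missing = sorted(leafset - by_label.keys())
    if missing:
        raise LookupLabelError(f"labels not in tree: {missing}")

    marked: set[int] = set()
    total = 0.0
    for label in leafset:
        node: TreeNode | None = by_label[label]
        while node is not None and node.parent is not None:
            if id(node) in marked:
                break
            marked.add(id(node))
            total += node.length
            node = node.parent
    if mode == "root":
        return total
    # subtract the root-to-MRCA path
    mrca = tree.mrca(leafset)
    node = mrca
    while node.parent is not None:
        total -= node.length
        node = node.parent
    return float(total)


class BranchTable:
    """Per-branch lengths, descendant leaf masks and grid-cell ranges.

    Built once per (tree, presence) pair and reused across cells: the range
    of branch ``b`` is the set of cells where at least one descendant of the
    branch occurs, and endemism divides each branch length by the size of
    that range.
    """

    def __init__(self, tree: RootedTree, presence: np.ndarray,
                 species: list[str]):
        """``presence``: cells × species boolean occupancy."""
        presence = np.asarray(presence, dtype=bool)
        occurring = [s for i, s in enumerate(species) if presence[:, i].any()]
        leaf_labels = set(tree.leaf_labels)
        missing = sorted(set(occurring) - leaf_labels)
        if missing:
            raise LookupLabelError(
                f"species missing from tree: {missing}"
            )
        self.tree = tree
        self.species = list(species)
        col_of = {s: j for j, s in enumerate(species)}

        nodes = [n for n in tree.postorder()]
        index = {id(n): i for i, n in enumerate(nodes)}
        n_nodes = len(nodes)
        n_sp = len(species)
        # descendant leaf mask per node (over the presence matrix's columns)
        desc = np.zeros((n_nodes, n_sp), dtype=bool)
        for i, node in enumerate(nodes):
            if node.is_leaf:
                j = col_of.get(node.label)
                if j is not None:
                    desc[i, j] = True
            else:
                for child in node.children:
                    desc[i] |= desc[index[id(child)]]
        self.nodes = nodes
        self.node_index = index
        self.desc = desc
        self.lengths = np.array(
            [n.length if n.parent is not None else 0.0 for n in nodes]
        )
        self.is_branch = np.array([n.parent is not None for n in nodes])
        # cells × nodes: does any descendant of the node occur in the cell?
        self.node_in_cell = (
            presence.astype(np.float64) @ desc.T.astype(np.float64)
        ) > 0.5
        self.range_size = self.node_in_cell.sum(axis=0)
        depths = tree.node_depths()
        self.depth = np.array([depths[id(n)] for n in nodes])
        self.presence = presence

    def mrca_index(self, cell: int) -> int:
        """Node index of the MRCA of the species present in ``cell``."""
        richness = int(self.presence[cell].sum())
        if richness == 0:
            raise ValueError(f"cell {cell} is empty")
        counts = self.desc.astype(np.int64) @ self.presence[cell].astype(np.int64)
        candidates = np.flatnonzero(counts == richness)
        return int(candidates[np.argmax(self.depth[candidates])])

    def pd_per_cell(self, mode: str = "root") -> np.ndarray:
        """Branch-sum diversity for every cell; NaN for empty cells."""
        _check_mode(mode)
        values = self.node_in_cell @ (self.lengths * self.is_branch)
        empty = ~self.presence.any(axis=1)
        values = values.astype(float)
        if mode == "mrca":
            for c in np.flatnonzero(~empty):
                values[c] -= self.depth[self.mrca_index(c)]
        values[empty] = np.nan
        return values

    def endemism_per_cell(self, mode: str = "root") -> np.ndarray:
        """Range-weighted endemism per cell; NaN for empty cells."""
        _check_mode(mode)
        contrib = np.zeros_like(self.lengths)
        live = self.is_branch & (self.range_size > 0)
        contrib[live] = self.lengths[live] / self.range_size[live]
        values = (self.node_in_cell @ contrib).astype(float)
        empty = ~self.presence.any(axis=1)
        if mode == "mrca":
            for c in np.flatnonzero(~empty):
                node = self.nodes[self.mrca_index(c)]
                while node.parent is not None:
                    i = self.node_index[id(node)]
                    values[c] -= contrib[i]
                    node = node.parent
        values[empty] = np.nan
        return values


def range_weighted_endemism(
    tree: RootedTree, presence: np.ndarray, species: list[str],
    mode: str = "root",
) -> np.ndarray:
    """Per-cell range-weighted endemism (PE on a phylogeny, FE on a
    functional dendrogram): sum over spanning branches of L_b / |r_b|."""
    return BranchTable(tree, presence, species).endemism_per_cell(mode=mode)


def _check_mode(mode: str) -> None:
    if mode not in ("root", "mrca"):
        raise ValueError(f"mode must be 'root' or 'mrca', got {mode!r}")
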