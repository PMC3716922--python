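"""Data model and elementary operations for multi-labeled phylogenetic trees.

A MUL-tree is an unrooted tree whose leaves carry taxon labels, where two or
more leaves may share the same label (e.g. several gene copies sampled from one
species).  Internal nodes are anonymous and must have degree at least three;
topology plus the leaf -> label map is all that matters.

This module provides the :class:`MULTree` container (a thin wrapper around a
``networkx`` graph), Newick I/O that tolerates duplicate leaf labels, the
prune/contract edit operations, per-edge label partitions, and an AHU-style
canonical form used to decide isomorphism between MUL-trees.
"""

from __future__ import annotations

import io
import json
import re
from collections import Counter
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, Iterator, List, Optional, Sequence, Tuple

import dendropy
import networkx as nx

__all__ = [
    "MULTree",
    "EdgePartition",
    "PartitionCounts",
    "NewickParseError",
    "InvalidTreeError",
    "StaleCountsError",
    "parse_newick",
    "iter_newick",
    "write_newick",
    "normalize",
    "distinct_labels",
    "multiplicity",
    "prune_leaf",
    "contract_edge",
    "edge_partition",
    "all_partition_counts",
    "canonical_form",
    "is_isomorphic",
]


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed."""


class InvalidTreeError(ValueError):
    """Raised when a structure violates the MUL-tree invariants."""


class StaleCountsError(RuntimeError):
    """Raised when partition counts are used after the tree was modified."""


_WS = re.compile(r"\s+")


def _clean_label(label: str) -> str:
    """Normalize a taxon label: strip, map internal whitespace to ``_``."""
    label = _WS.sub("_", label.strip())
    if not label:
        raise InvalidTreeError("empty leaf label")
    return label


class MULTree:
    """An unrooted multi-labeled tree.

    Nodes are opaque integer identities.  ``leaf_label`` maps each leaf node to
    its taxon label; internal nodes carry no label.  The empty tree (zero
    nodes) is representable: it is the result of reducing a tree with no
    conflict-free quartet information.
    """

    __slots__ = ("graph", "leaf_label", "_version", "_next_id")

    def __init__(self) -> None:
        self.graph: nx.Graph = nx.Graph()
        self.leaf_label: Dict[int, str] = {}
        self._version = 0
        self._next_id = 0

    # -- construction ------------------------------------------------------

    def new_node(self, label: Optional[str] = None) -> int:
        node = self._next_id
        self._next_id += 1
        self.graph.add_node(node)
        if label is not None:
            self.leaf_label[node] = label
        self._version += 1
        return node

    def add_edge(self, u: int, v: int) -> None:
        self.graph.add_edge(u, v)
        self._version += 1

    def copy(self) -> "MULTree":
        other = MULTree()
        other.graph = self.graph.copy()
        other.leaf_label = dict(self.leaf_label)
        other._next_id = self._next_id
        return other

    # -- basic queries -----------------------------------------------------

    @property
    def version(self) -> int:
        return self._version

    def is_empty(self) -> bool:
        return self.graph.number_of_nodes() == 0

    def is_leaf(self, node: int) -> bool:
        return node in self.leaf_label

    def leaves(self) -> List[int]:
        return sorted(self.leaf_label)

    def n_leaves(self) -> int:
        return len(self.leaf_label)

    def labels(self) -> FrozenSet[str]:
        """The label set M (distinct taxon names)."""
        return frozenset(self.leaf_label.values())

    def label_multiplicity(self) -> Counter:
        return Counter(self.leaf_label.values())

    def degree(self, node: int) -> int:
        return self.graph.degree[node]

    def neighbors(self, node: int) -> List[int]:
        return sorted(self.graph.neighbors(node))

    def edges(self) -> List[Tuple[int, int]]:
        """All edges as (min, max) node pairs, deterministically ordered."""
        return sorted(tuple(sorted(e)) for e in self.graph.edges)

    def internal_edges(self) -> List[Tuple[int, int]]:
        return [
            (u, v)
            for u, v in self.edges()
            if u not in self.leaf_label and v not in self.leaf_label
        ]

    def pendant_nodes(self) -> List[int]:
        """Internal nodes adjacent to at least one leaf."""
        out = set()
        for leaf in self.leaf_label:
            for nb in self.graph.neighbors(leaf):
                if nb not in self.leaf_label:
                    out.add(nb)
        return sorted(out)

    def leaves_with_label(self, label: str) -> List[int]:
        return sorted(n for n, lab in self.leaf_label.items() if lab == label)

    # -- invariants --------------------------------------------------------

    def validate(self) -> None:
        """Raise :class:`InvalidTreeError` if any MUL-tree invariant fails."""
        g = self.graph
        if g.number_of_nodes() == 0:
            return
        if not nx.is_tree(g):
            raise InvalidTreeError("graph is not connected and acyclic")
        for node in g:
            deg = g.degree[node]
            if node in self.leaf_label:
                if deg > 1:
                    raise InvalidTreeError(f"leaf {node} has degree {deg} > 1")
            else:
                if deg < 3:
                    raise InvalidTreeError(
                        f"internal node {node} has degree {deg} < 3"
                    )
        extra = set(self.leaf_label) - set(g)
        if extra:
            raise InvalidTreeError(f"leaf labels for absent nodes: {extra}")

    # -- in-place edits (used by the reduction engine) ---------------------

    def _suppress_if_degree_two(self, node: int) -> None:
        if node in self.leaf_label or node not in self.graph:
            return
        if self.graph.degree[node] == 2:
            a, b = self.graph.neighbors(node)
            self.graph.remove_node(node)
            self.graph.add_edge(a, b)
            self._version += 1

    def prune_leaf_inplace(self, leaf: int) -> None:
        """Delete ``leaf``; suppress its neighbor if it drops to degree two."""
        if leaf not in self.leaf_label:
            raise InvalidTreeError(f"node {leaf} is not a leaf")
        nbs = list(self.graph.neighbors(leaf))
        self.graph.remove_node(leaf)
        del self.leaf_label[leaf]
        self._version += 1
        if nbs:
            nb = nbs[0]
            if nb not in self.leaf_label:
                deg = self.graph.degree[nb]
                if deg == 2:
                    self._suppress_if_degree_two(nb)
                elif deg <= 1:
                    # an internal node left with < 2 neighbors can only arise
                    # on degenerate (tiny) trees; drop it and keep the rest
                    self.graph.remove_node(nb)
                    self._version += 1

    def contract_edge_inplace(self, u: int, v: int) -> None:
        """Contract internal edge (u, v): merge v into u."""
        if not self.graph.has_edge(u, v):
            raise InvalidTreeError(f"no edge ({u}, {v})")
        if u in self.leaf_label or v in self.leaf_label:
            raise InvalidTreeError(
                "contraction is defined only for internal edges"
            )
        for w in list(self.graph.neighbors(v)):
            if w != u:
                self.graph.add_edge(u, w)
        self.graph.remove_node(v)
        self._version += 1

    def delete_nodes_inplace(self, nodes: Iterable[int]) -> None:
        for node in nodes:
            if node in self.graph:
                self.graph.remove_node(node)
                self.leaf_label.pop(node, None)
        self._version += 1


# ---------------------------------------------------------------------------
# Newick I/O (dendropy-backed; duplicate leaf labels parse as node labels)
# ---------------------------------------------------------------------------

_DENDROPY_KW = dict(
    schema="newick",
    suppress_internal_node_taxa=True,
    suppress_leaf_node_taxa=True,
    preserve_underscores=True,
)


def _from_dendropy(dtree: "dendropy.Tree") -> MULTree:
    tree = MULTree()
    node_map: Dict[object, int] = {}
    any_leaf = False
    for dnode in dtree.preorder_node_iter():
        if dnode.is_leaf():
            label = dnode.label
            if label is None and dnode.taxon is not None:
                label = dnode.taxon.label
            if label is None:
                raise NewickParseError("tree contains an unlabeled leaf")
            node = tree.new_node(_clean_label(str(label)))
            any_leaf = True
        else:
            node = tree.new_node()
        node_map[dnode] = node
        if dnode.parent_node is not None:
            tree.add_edge(node_map[dnode.parent_node], node)
    if not any_leaf:
        raise NewickParseError("tree has no labeled leaves")
    return tree


def iter_newick(text: str) -> Iterator[MULTree]:
    """Yield normalized MUL-trees from a (possibly multi-tree) Newick string.

    Trees may be separated by newlines or simply by their ``;`` terminators.
    Branch lengths and internal node names are parsed and discarded; duplicate
    leaf labels are allowed.
    """
    stream = io.StringIO(text)
    try:
        for dtree in dendropy.Tree.yield_from_files(
            files=[stream], **_DENDROPY_KW
        ):
            yield normalize(_from_dendropy(dtree))
    except dendropy.utility.error.DataParseError as exc:
        raise NewickParseError(str(exc)) from exc


def parse_newick(text: str) -> List[MULTree]:
    """Parse one or more Newick tree statements into normalized MUL-trees."""
    trees = list(iter_newick(text))
    if not trees:
        raise NewickParseError("no tree statement found")
    return trees


def write_newick(tree: MULTree) -> str:
    """Serialize a normalized MUL-tree to a Newick string (no branch lengths).

    The empty tree is written as the conventional empty statement ``";"``.
    Round trip: ``parse_newick(write_newick(t))[0]`` is isomorphic to ``t``.
    """
    if tree.is_empty():
        return ";"
    dtree = dendropy.Tree()
    tns = dtree.taxon_namespace

    # Root at the smallest-id internal node (deterministic); tiny trees with
    # no internal node are rooted at the smallest leaf.
    internals = [n for n in sorted(tree.graph) if not tree.is_leaf(n)]
    root = internals[0] if internals else min(tree.graph)

    def attach(dnode: "dendropy.Node", node: int) -> None:
        if tree.is_leaf(node):
            dnode.taxon = tns.new_taxon(label=tree.leaf_label[node])

    root_dnode = dtree.seed_node
    attach(root_dnode, root)
    stack = [(root, None, root_dnode)]
    while stack:
        node, parent, dnode = stack.pop()
        for child in tree.neighbors(node):
            if child == parent:
                continue
            dchild = dendropy.Node()
            attach(dchild, child)
            dnode.add_child(dchild)
            stack.append((child, node, dchild))
    text = dtree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    )
    return text.strip()


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def _normalize_inplace(tree: MULTree) -> None:
    g = tree.graph
    changed = True
    while changed:
        changed = False
        for node in list(g):
            if node in tree.leaf_label:
                continue
            deg = g.degree[node]
            if deg <= 1:
                g.remove_node(node)  # dangling root artifact
                changed = True
            elif deg == 2:
                a, b = g.neighbors(node)
                g.remove_node(node)
                g.add_edge(a, b)
                changed = True
    tree._version += 1


def normalize(tree: MULTree) -> MULTree:
    """Return the fully normalized form of a raw parsed tree.

    Degree-two internal nodes (including a rooted binary tree's root) are
    suppressed and dangling unlabeled nodes removed, so that every internal
    node has degree >= 3.  Idempotent.
    """
    out = tree.copy()
    _normalize_inplace(out)
    out.validate()
    return out


def distinct_labels(tree: MULTree) -> FrozenSet[str]:
    """The set M of distinct taxon labels on the tree."""
    return tree.labels()


def multiplicity(tree: MULTree) -> Dict[str, int]:
    """Label -> number of leaves bearing it.  Labels with multiplicity >= 2
    are the MUL-taxa."""
    return dict(tree.label_multiplicity())


# ---------------------------------------------------------------------------
# Edit operations (pure wrappers over the in-place methods)
# ---------------------------------------------------------------------------


def prune_leaf(tree: MULTree, leaf: int) -> MULTree:
    """Delete a leaf, suppressing its neighbor if it drops to degree two."""
    out = tree.copy()
    out.prune_leaf_inplace(leaf)
    return out


def contract_edge(tree: MULTree, edge: Tuple[int, int]) -> MULTree:
    """Contract an internal edge: delete it and identify its endpoints."""
    out = tree.copy()
    out.contract_edge_inplace(*edge)
    return out


# ---------------------------------------------------------------------------
# Per-edge label partitions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EdgePartition:
    """For edge (u, v): labels exclusive to each side and common to both.

    ``m_u``, ``m_v`` and ``common`` are pairwise disjoint and their union is
    the full label set M of the tree.
    """

    m_u: FrozenSet[str]
    m_v: FrozenSet[str]
    common: FrozenSet[str]


def _side_nodes(tree: MULTree, start: int, blocked: int) -> List[int]:
    """Nodes of the component containing ``start`` when edge to ``blocked``
    is removed."""
    seen = {blocked, start}
    stack = [start]
    out = [start]
    while stack:
        node = stack.pop()
        for nb in tree.graph.neighbors(node):
            if nb not in seen:
                seen.add(nb)
                out.append(nb)
                stack.append(nb)
    return out


def edge_partition(tree: MULTree, edge: Tuple[int, int]) -> EdgePartition:
    """Partition of the label set induced by ``edge`` = (u, v)."""
    u, v = edge
    if not tree.graph.has_edge(u, v):
        raise InvalidTreeError(f"no edge ({u}, {v})")
    labels_u = {
        tree.leaf_label[n]
        for n in _side_nodes(tree, u, v)
        if n in tree.leaf_label
    }
    labels_v = {
        tree.leaf_label[n]
        for n in _side_nodes(tree, v, u)
        if n in tree.leaf_label
    }
    common = labels_u & labels_v
    return EdgePartition(
        m_u=frozenset(labels_u - common),
        m_v=frozenset(labels_v - common),
        common=frozenset(common),
    )


class PartitionCounts:
    """Per-directed-edge distinct-label sets, packed as bitmasks.

    For every directed edge (u, v), ``side_mask[(u, v)]`` is the bitmask over
    the label set of the labels appearing on the v-side of the edge.  From
    these, the exclusive-side sets M_u / M_v, the common set C, and their
    cardinalities are all O(|M|/64) bit operations.  Computed in two tree
    traversals.

    Counts are tied to the tree's modification counter; using them after the
    tree changes raises :class:`StaleCountsError`.
    """

    def __init__(self, tree: MULTree) -> None:
        self._tree = tree
        self._tree_version = tree.version
        self.label_list: List[str] = sorted(tree.labels())
        self.label_bit: Dict[str, int] = {
            lab: 1 << i for i, lab in enumerate(self.label_list)
        }
        self.full_mask = (1 << len(self.label_list)) - 1
        self.side_mask: Dict[Tuple[int, int], int] = {}
        self._compute()

    # -- construction ------------------------------------------------------

    def _compute(self) -> None:
        tree = self._tree
        g = tree.graph
        if g.number_of_nodes() <= 1:
            return
        root = min(g)
        parent: Dict[int, Optional[int]] = {root: None}
        order = [root]
        for node in order:
            for nb in g.neighbors(node):
                if nb not in parent:
                    parent[nb] = node
                    order.append(nb)
        down: Dict[int, int] = {}
        children: Dict[int, List[int]] = {n: [] for n in order}
        for node in order[1:]:
            children[parent[node]].append(node)
        for node in reversed(order):
            mask = 0
            if node in tree.leaf_label:
                mask |= self.label_bit[tree.leaf_label[node]]
            for child in children[node]:
                mask |= down[child]
            down[node] = mask
        up: Dict[int, int] = {root: 0}
        for node in order:
            base = up[node]
            if node in tree.leaf_label:
                base |= self.label_bit[tree.leaf_label[node]]
            kids = children[node]
            k = len(kids)
            prefix = [0] * (k + 1)
            for i, child in enumerate(kids):
                prefix[i + 1] = prefix[i] | down[child]
            suffix = 0
            for i in range(k - 1, -1, -1):
                child = kids[i]
                up[child] = base | prefix[i] | suffix
                suffix |= down[child]
        for node in order[1:]:
            p = parent[node]
            self.side_mask[(p, node)] = down[node]
            self.side_mask[(node, p)] = up[node]

    # -- queries -----------------------------------------------------------

    def check_fresh(self) -> None:
        if self._tree.version != self._tree_version:
            raise StaleCountsError(
                "tree modified since partition counts were computed"
            )

    def side_labels_mask(self, u: int, v: int) -> int:
        """Bitmask of all labels on the u-side of edge (u, v)."""
        self.check_fresh()
        return self.side_mask[(v, u)]

    def exclusive_mask(self, u: int, v: int) -> int:
        """Bitmask of M_u^{uv}: labels exclusive to the u-side of (u, v)."""
        self.check_fresh()
        return self.side_mask[(v, u)] & ~self.side_mask[(u, v)]

    def common_mask(self, u: int, v: int) -> int:
        self.check_fresh()
        return self.side_mask[(v, u)] & self.side_mask[(u, v)]

    def n_distinct(self, u: int, v: int) -> int:
        """n_u^{uv}: number of distinct labels on the u-side of (u, v)."""
        return self.side_labels_mask(u, v).bit_count()

    def m_exclusive(self, u: int, v: int) -> int:
        """|M_u^{uv}|: labels exclusive to the u-side of (u, v)."""
        return self.exclusive_mask(u, v).bit_count()

    def labels_from_mask(self, mask: int) -> FrozenSet[str]:
        out = []
        while mask:
            low = mask & -mask
            out.append(self.label_list[low.bit_length() - 1])
            mask ^= low
        return frozenset(out)


def all_partition_counts(tree: MULTree) -> PartitionCounts:
    """Distinct/exclusive label counts for every directed edge of the tree."""
    return PartitionCounts(tree)


# ---------------------------------------------------------------------------
# Canonical form / isomorphism
# ---------------------------------------------------------------------------


def _centroids(tree: MULTree) -> List[int]:
    g = tree.graph
    n = g.number_of_nodes()
    root = min(g)
    parent: Dict[int, Optional[int]] = {root: None}
    order = [root]
    for node in order:
        for nb in g.neighbors(node):
            if nb not in parent:
                parent[nb] = node
                order.append(nb)
    size = {node: 1 for node in order}
    for node in reversed(order[1:]):
        size[parent[node]] += size[node]
    best: List[int] = []
    best_val = n + 1
    for node in order:
        heaviest = n - size[node]
        for nb in g.neighbors(node):
            if nb != parent[node]:
                heaviest = max(heaviest, size[nb])
        if heaviest < best_val:
            best_val = heaviest
            best = [node]
        elif heaviest == best_val:
            best.append(node)
    return best


def _rooted_signature(tree: MULTree, root: int, block: Optional[int]) -> str:
    """AHU-style signature of the subtree at ``root`` looking away from
    ``block``; invariant under child reordering."""
    sig: Dict[int, str] = {}
    stack: List[Tuple[int, Optional[int], bool]] = [(root, block, False)]
    while stack:
        node, parent, expanded = stack.pop()
        kids = [nb for nb in tree.neighbors(node) if nb != parent]
        if node in tree.leaf_label and not kids:
            sig[node] = "L" + json.dumps(tree.leaf_label[node])
            continue
        if not expanded:
            stack.append((node, parent, True))
            for child in kids:
                stack.append((child, node, False))
        else:
            parts = sorted(sig[child] for child in kids)
            own = ""
            if node in tree.leaf_label:  # labeled node used as root
                own = "L" + json.dumps(tree.leaf_label[node])
            sig[node] = own + "(" + ",".join(parts) + ")"
    return sig[root]


def canonical_form(tree: MULTree) -> str:
    """Canonical text form: equal strings iff the trees are isomorphic as
    unrooted leaf-labeled (multiset) trees.

    The tree is rooted at its centroid (or, for a centroid pair, at the
    midpoint of the centroid edge) and subtree signatures are sorted
    recursively.
    """
    if tree.is_empty():
        return ";"
    if tree.graph.number_of_nodes() == 1:
        node = next(iter(tree.graph))
        return "L" + json.dumps(tree.leaf_label[node])
    cents = _centroids(tree)
    if len(cents) == 1:
        return _rooted_signature(tree, cents[0], None)
    a, b = cents
    sigs = sorted(
        (_rooted_signature(tree, a, b), _rooted_signature(tree, b, a))
    )
    return "[" + ",".join(sigs) + "]"


def is_isomorphic(t1: MULTree, t2: MULTree) -> bool:
    """Isomorphism of normalized MUL-trees (topology + leaf label multiset)."""
    return canonical_form(t1) == canonical_form(t2)
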