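"""Quartet semantics for MUL-trees.

The smallest informative phylogenetic statement on a label set is a quartet
topology ``ab|cd``: an unordered bipartition of four distinct labels into two
pairs.  An edge (u, v) of a MUL-tree *resolves* ``ab|cd`` when ``a`` and ``b``
are exclusive to the u-side and ``c`` and ``d`` exclusive to the v-side; the
set of quartets an edge resolves is its information content Delta(u, v), and
the information content I(T) of the tree is the union over all edges.  I(T)
is conflict-free: no two of its quartets place the same four labels in
different topologies, and there is always a singly-labeled tree displaying
all of I(T) (obtained by relabeling duplicate leaves with fresh names).

Everything here is brute-force and explicit; it is the semantic ground truth
(and test oracle) that the reduction engine in :mod:`mulred.reduce` must
preserve, and is intended for trees with a moderate number of distinct
labels (the label set enters as O(|M|^4)).
"""

from __future__ import annotations

from itertools import combinations
from typing import Dict, FrozenSet, Iterable, List, NamedTuple, Set, Tuple

from .core import (
    MULTree,
    InvalidTreeError,
    PartitionCounts,
    all_partition_counts,
)

__all__ = [
    "Quartet",
    "QuartetSet",
    "delta",
    "information_content",
    "is_informative",
    "assert_conflict_free",
    "relabel_to_singly",
    "conflicting_label_sets",
    "quartets_to_text",
]


class Quartet(NamedTuple):
    """Canonical unordered bipartition ``ab|cd`` of four distinct labels.

    Each side is internally sorted and the sides are ordered
    lexicographically, so equal topologies compare and hash equal.
    """

    side_a: Tuple[str, str]
    side_b: Tuple[str, str]

    @classmethod
    def of(cls, a: str, b: str, c: str, d: str) -> "Quartet":
        if len({a, b, c, d}) != 4:
            raise ValueError("quartet labels must be pairwise distinct")
        p = (a, b) if a < b else (b, a)
        q = (c, d) if c < d else (d, c)
        return cls(p, q) if p <= q else cls(q, p)

    @property
    def support(self) -> FrozenSet[str]:
        """The underlying 4-label set."""
        return frozenset(self.side_a) | frozenset(self.side_b)

    def __str__(self) -> str:
        return f"{self.side_a[0]},{self.side_a[1]}|{self.side_b[0]},{self.side_b[1]}"


QuartetSet = Set[Quartet]


def _pairs(labels: Iterable[str]) -> List[Tuple[str, str]]:
    return list(combinations(sorted(labels), 2))


def _delta_from_sets(
    m_u: Iterable[str], m_v: Iterable[str]
) -> QuartetSet:
    out: QuartetSet = set()
    for a, b in _pairs(m_u):
        for c, d in _pairs(m_v):
            out.add(Quartet.of(a, b, c, d))
    return out


def delta(tree: MULTree, edge: Tuple[int, int]) -> QuartetSet:
    """Delta(u, v): quartets resolved by ``edge`` — all pairs from the
    u-exclusive label set against all pairs from the v-exclusive set.

    Size is C(|M_u|, 2) * C(|M_v|, 2); empty whenever either exclusive side
    has fewer than two labels.
    """
    u, v = edge
    if not tree.graph.has_edge(u, v):
        raise InvalidTreeError(f"no edge ({u}, {v})")
    counts = all_partition_counts(tree)
    m_u = counts.labels_from_mask(counts.exclusive_mask(u, v))
    m_v = counts.labels_from_mask(counts.exclusive_mask(v, u))
    return _delta_from_sets(m_u, m_v)


def is_informative(tree: MULTree, edge: Tuple[int, int]) -> bool:
    """True iff both exclusive sides of the edge hold >= 2 labels, i.e.
    Delta(edge) is non-empty."""
    u, v = edge
    if not tree.graph.has_edge(u, v):
        raise InvalidTreeError(f"no edge ({u}, {v})")
    counts = all_partition_counts(tree)
    return counts.m_exclusive(u, v) >= 2 and counts.m_exclusive(v, u) >= 2


def information_content(tree: MULTree) -> QuartetSet:
    """I(T): union of Delta over every edge (pendant edges included).

    Empty for trees with fewer than four distinct labels.
    """
    out: QuartetSet = set()
    if tree.is_empty() or len(tree.labels()) < 4:
        return out
    counts = all_partition_counts(tree)
    seen_pairs: Set[Tuple[int, int]] = set()
    for u, v in tree.edges():
        mu = counts.exclusive_mask(u, v)
        mv = counts.exclusive_mask(v, u)
        if mu.bit_count() < 2 or mv.bit_count() < 2:
            continue
        key = (mu, mv) if mu < mv else (mv, mu)
        if key in seen_pairs:  # identical partition ⇒ identical Delta
            continue
        seen_pairs.add(key)
        out |= _delta_from_sets(
            counts.labels_from_mask(mu), counts.labels_from_mask(mv)
        )
    return out


def assert_conflict_free(qs: QuartetSet) -> bool:
    """True iff no two quartets in ``qs`` put the same four labels into
    different topologies."""
    seen: Dict[FrozenSet[str], Quartet] = {}
    for q in qs:
        prev = seen.setdefault(q.support, q)
        if prev != q:
            return False
    return True


def relabel_to_singly(tree: MULTree, keep_policy: str = "first-dfs") -> MULTree:
    """Relabel duplicate leaves with fresh unique names (``l#2``, ``l#3`` ...)
    so the result is singly labeled.

    The leaf keeping the original name is the first copy met in a
    deterministic depth-first traversal.  The information content can only
    grow: I(tree) is a subset of I(result).
    """
    if keep_policy != "first-dfs":
        raise ValueError(f"unknown keep policy: {keep_policy}")
    out = tree.copy()
    if out.is_empty():
        return out
    existing = set(out.leaf_label.values())
    seen_count: Dict[str, int] = {}
    # deterministic DFS over the whole tree from the smallest node id
    root = min(out.graph)
    stack = [(root, None)]
    while stack:
        node, parent = stack.pop()
        if node in out.leaf_label:
            lab = out.leaf_label[node]
            k = seen_count.get(lab, 0) + 1
            seen_count[lab] = k
            if k > 1:
                fresh = f"{lab}#{k}"
                if fresh in existing:
                    raise InvalidTreeError(
                        f"fresh label {fresh!r} collides with an existing label"
                    )
                out.leaf_label[node] = fresh
        for nb in reversed(out.neighbors(node)):
            if nb != parent:
                stack.append((nb, node))
    out._version += 1
    return out


def conflicting_label_sets(tree: MULTree) -> Set[FrozenSet[str]]:
    """4-label sets on which the tree displays two or more topologies
    *leafwise*: edge e displays ``ab|cd`` leafwise when some leaves labeled
    a, b lie on one side of e and some labeled c, d on the other.

    Duplicate labels make leafwise display weaker than formal resolution
    (a common label may be used on either side), which is exactly how
    conflicting topologies arise.  Singly-labeled trees report nothing.
    """
    out: Set[FrozenSet[str]] = set()
    if tree.is_empty() or len(tree.labels()) < 4:
        return out
    topologies: Dict[FrozenSet[str], Set[Quartet]] = {}
    counts = all_partition_counts(tree)
    seen_sides: Set[Tuple[int, int]] = set()
    for u, v in tree.edges():
        su = counts.side_labels_mask(u, v)
        sv = counts.side_labels_mask(v, u)
        key = (su, sv) if su < sv else (sv, su)
        if key in seen_sides:
            continue
        seen_sides.add(key)
        labels_u = counts.labels_from_mask(su)
        labels_v = counts.labels_from_mask(sv)
        for a, b in _pairs(labels_u):
            for c, d in _pairs(labels_v):
                if len({a, b, c, d}) != 4:
                    continue
                q = Quartet.of(a, b, c, d)
                topologies.setdefault(q.support, set()).add(q)
    for support, qs in topologies.items():
        if len(qs) >= 2:
            out.add(support)
    return out


def quartets_to_text(qs: QuartetSet) -> str:
    """Sorted one-per-line ``a,b|c,d`` rendering, for diffing."""
    return "\n".join(sorted(str(q) for q in qs))
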