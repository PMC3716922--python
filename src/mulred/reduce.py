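"""Reduction of a MUL-tree to its maximally reduced form (MRF).

A leaf is *prunable* and an internal edge *contractible* when removing it
leaves the tree's conflict-free quartet information content I(T) unchanged.
The MRF is the tree obtained by applying such information-preserving edits
until none applies; it is unique (independent of the edit order), so it can
serve as a canonical representative of the equivalence class of all MUL-trees
sharing the same information content.

The production reducer :func:`mrf` runs the quadratic-time three-phase
pipeline:

1. contract internal edges with an exclusive side of at most one label
   (they resolve no quartet);
2. repeatedly locate adjacent internal edges whose quartet sets are
   comparable — decidable in constant time from per-edge exclusive-label
   counts — contract the less informative one, collapse the internal edges of
   subtrees branching off the shared node, and delete those subtrees outright
   when the two quartet sets are equal;
3. prune leaves of labels that participate in no resolved quartet, deduplicate
   same-labeled leaves sharing a pendant node, and prune duplicate-label
   leaves attached at degree->=3 nodes of the label's spanning subtree.

The pipeline is repeated until a full pass makes no change, so the returned
tree is a verified fixed point.  :func:`reference_mrf` is an independent
brute-force reducer (it literally retries every prune/contract and keeps
those that preserve I, recomputed from scratch) used as a small-scale oracle.

:func:`restrict_to_unique_labels` implements the optional second step that
drops every multiply-labeled taxon from the MRF, yielding a singly-labeled
tree for downstream methods that require one.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

from .core import (
    MULTree,
    InvalidTreeError,
    PartitionCounts,
    _side_nodes,
    is_isomorphic,
)
from .quartets import information_content

__all__ = [
    "ReductionReport",
    "EQUAL",
    "INNER_SUBSET",
    "OUTER_SUBSET",
    "INCOMPARABLE",
    "contract_uninformative",
    "edge_subsumption",
    "contract_subsumed",
    "prune_uninvolved_labels",
    "dedupe_sibling_leaves",
    "prune_spanning_redundant",
    "mrf",
    "reference_mrf",
    "restrict_to_unique_labels",
    "reduce_two_step",
]


@dataclass
class ReductionReport:
    """Accounting of one reduction run.

    Taxon losses are percentages of the *distinct* input labels (taxa), not
    of leaf copies.  ``taxa_lost_step2_pct`` is filled only by
    :func:`reduce_two_step`.  ``no_information`` is True iff the MRF is the
    empty tree, i.e. the input resolved no conflict-free quartet.
    """

    phase1_contractions: int = 0
    phase2_contractions: int = 0
    subtrees_deleted: int = 0
    leaves_pruned: Dict[str, int] = field(
        default_factory=lambda: {
            "no_quartet_label": 0,
            "pendant_dedupe": 0,
            "spanning_rule": 0,
        }
    )
    taxa_lost_step1_pct: float = 0.0
    taxa_lost_step2_pct: Optional[float] = None
    no_information: bool = False

    def to_dict(self) -> dict:
        return {
            "phase1Contractions": self.phase1_contractions,
            "phase2Contractions": self.phase2_contractions,
            "subtreesDeleted": self.subtrees_deleted,
            "leavesPruned": {
                "noQuartetLabel": self.leaves_pruned["no_quartet_label"],
                "pendantDedupe": self.leaves_pruned["pendant_dedupe"],
                "spanningRule": self.leaves_pruned["spanning_rule"],
            },
            "taxaLostStep1": self.taxa_lost_step1_pct,
            "taxaLostStep2": self.taxa_lost_step2_pct,
            "noInformation": self.no_information,
        }


# ---------------------------------------------------------------------------
# Edge subsumption (constant-time Delta comparison from counts)
# ---------------------------------------------------------------------------

EQUAL = "equal"
INNER_SUBSET = "inner_subset"
OUTER_SUBSET = "outer_subset"
INCOMPARABLE = "incomparable"


def edge_subsumption(
    tree: MULTree,
    counts: PartitionCounts,
    inner_edge: Tuple[int, int],
    outer_edge: Tuple[int, int],
) -> str:
    """Compare Delta(inner_edge) and Delta(outer_edge) using only exclusive
    label counts.

    Any two distinct edges of a tree lie on a common path; orient the path as
    (u, v, ..., w, x) with inner = (u, v) and outer = (w, x).  Then
    Delta(inner) is a subset of Delta(outer) iff the far-side exclusive
    counts |M_v| and |M_x| agree, and the two are equal iff the near-side
    counts |M_u| and |M_w| agree as well (nestedness of the sides makes
    cardinality equality equivalent to set equality).

    Returns ``"equal"``, ``"inner_subset"`` (Delta(inner) subset of
    Delta(outer), not detected equal), ``"outer_subset"``, or
    ``"incomparable"``.  Raises :class:`StaleCountsError` if the tree was
    modified after ``counts`` was computed.

    A reported subset/equality always holds; ``"incomparable"`` is
    conclusive only when both edges are informative (an empty Delta nests in
    anything without the counts matching).  The reduction applies this test
    after uninformative edges have been contracted, where it is exact.
    """
    counts.check_fresh()
    a, b = inner_edge
    c, d = outer_edge
    if not tree.graph.has_edge(a, b) or not tree.graph.has_edge(c, d):
        raise InvalidTreeError("both edges must exist in the tree")
    if frozenset(inner_edge) == frozenset(outer_edge):
        return EQUAL
    # orient inner as (u, v) with v on the side containing the outer edge
    side_b = set(_side_nodes(tree, b, a))
    u, v = (a, b) if c in side_b and d in side_b else (b, a)
    side_d = set(_side_nodes(tree, d, c))
    w, x = (d, c) if u in side_d and v in side_d else (c, d)
    far_equal = counts.m_exclusive(v, u) == counts.m_exclusive(x, w)
    near_equal = counts.m_exclusive(u, v) == counts.m_exclusive(w, x)
    if far_equal and near_equal:
        return EQUAL
    if far_equal:
        return INNER_SUBSET
    if near_equal:
        return OUTER_SUBSET
    return INCOMPARABLE


# ---------------------------------------------------------------------------
# Phase 1: contract uninformative internal edges
# ---------------------------------------------------------------------------


def _contract_uninformative_inplace(tree: MULTree) -> int:
    internal = tree.internal_edges()
    if not internal:
        return 0
    counts = PartitionCounts(tree)
    doomed = [
        (u, v)
        for u, v in internal
        if counts.m_exclusive(u, v) <= 1 or counts.m_exclusive(v, u) <= 1
    ]
    # contracting one edge never changes another edge's bipartition, so the
    # whole batch can be contracted under one set of counts
    merged: Dict[int, int] = {}

    def find(n: int) -> int:
        while n in merged:
            n = merged[n]
        return n

    done = 0
    for u, v in doomed:
        ru, rv = find(u), find(v)
        if ru == rv or not tree.graph.has_edge(ru, rv):
            continue
        tree.contract_edge_inplace(ru, rv)
        merged[rv] = ru
        done += 1
    return done


def contract_uninformative(tree: MULTree) -> MULTree:
    """Contract every internal edge that resolves no quartet (an exclusive
    side with <= 1 label).  Pendant edges are never touched."""
    out = tree.copy()
    _contract_uninformative_inplace(out)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Phase 2: contract subsumed edges / delete redundant branching subtrees
# ---------------------------------------------------------------------------


def _branch_components(
    tree: MULTree, v: int, keep: Set[int]
) -> List[List[int]]:
    """Connected components hanging off ``v`` through neighbors not in
    ``keep`` (components do not include ``v``)."""
    comps = []
    for z in tree.neighbors(v):
        if z not in keep:
            comps.append(_side_nodes(tree, z, v))
    return comps


def _collapse_branch_internals(tree: MULTree, v: int, keep: Set[int]) -> int:
    """Contract all internal edges of subtrees branching off ``v``: their
    leaves end up attached directly to ``v``.  Returns contractions done.

    Merging the branch node nearest to ``v`` exposes the next one, so a
    simple sweep reaches every internal node of every branch."""
    done = 0
    while True:
        z = next(
            (
                z
                for z in tree.neighbors(v)
                if z not in keep and z not in tree.leaf_label
            ),
            None,
        )
        if z is None:
            return done
        tree.contract_edge_inplace(v, z)
        done += 1


def _delete_branches(tree: MULTree, v: int, keep: Set[int]) -> Tuple[int, int]:
    """Delete entire subtrees branching off ``v``.  Returns (number of
    subtrees deleted, leaves removed with them)."""
    comps = _branch_components(tree, v, keep)
    n_leaves = 0
    for comp in comps:
        n_leaves += sum(1 for n in comp if n in tree.leaf_label)
        tree.delete_nodes_inplace(comp)
    return len(comps), n_leaves


def _contract_subsumed_inplace(tree: MULTree, report: ReductionReport) -> bool:
    changed = False
    while True:
        internal_edges = tree.internal_edges()
        if len(internal_edges) < 2:
            break
        counts = PartitionCounts(tree)
        event = None
        for v in sorted(tree.graph):
            if v in tree.leaf_label:
                continue
            int_nbrs = [
                n for n in tree.neighbors(v) if n not in tree.leaf_label
            ]
            if len(int_nbrs) < 2:
                continue
            for i in range(len(int_nbrs)):
                for j in range(i + 1, len(int_nbrs)):
                    u, w = int_nbrs[i], int_nbrs[j]
                    # path u - v - w; far sides of (u,v) and (v,w) nest
                    far_eq = counts.m_exclusive(v, u) == counts.m_exclusive(
                        w, v
                    )
                    near_eq = counts.m_exclusive(u, v) == counts.m_exclusive(
                        v, w
                    )
                    if far_eq or near_eq:
                        event = (u, v, w, far_eq, near_eq)
                        break
                if event:
                    break
            if event:
                break
        if event is None:
            break
        u, v, w, far_eq, near_eq = event
        changed = True
        if far_eq and near_eq:
            # Delta(u,v) = Delta(v,w): subtrees branching off v carry no
            # information of their own — delete them, then v has degree two
            n_sub, _ = _delete_branches(tree, v, keep={u, w})
            report.subtrees_deleted += n_sub
            tree._suppress_if_degree_two(v)
            report.phase2_contractions += 1
        else:
            # strict containment: contract the less informative edge and the
            # internal edges of subtrees branching off v
            report.phase2_contractions += _collapse_branch_internals(
                tree, v, keep={u, w}
            )
            if far_eq:  # Delta(u,v) subset of Delta(v,w): contract (u,v)
                tree.contract_edge_inplace(u, v)
            else:  # Delta(v,w) subset of Delta(u,v): contract (v,w)
                tree.contract_edge_inplace(v, w)
            report.phase2_contractions += 1
    return changed


def contract_subsumed(tree: MULTree) -> MULTree:
    """Resolve all comparable adjacent edge pairs (Delta-subsumption); expects
    uninformative edges to have been contracted already."""
    out = tree.copy()
    _contract_subsumed_inplace(out, ReductionReport())
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Phase 3: prune redundant leaves
# ---------------------------------------------------------------------------


def _prune_uninvolved_inplace(tree: MULTree) -> int:
    if tree.is_empty():
        return 0
    counts = PartitionCounts(tree)
    participating = 0
    for u, v in tree.edges():
        mu = counts.exclusive_mask(u, v)
        mv = counts.exclusive_mask(v, u)
        if mu.bit_count() >= 2 and mv.bit_count() >= 2:
            participating |= mu | mv
    pruned = 0
    for leaf, label in sorted(tree.leaf_label.items()):
        if not counts.label_bit[label] & participating:
            if leaf in tree.leaf_label:
                tree.prune_leaf_inplace(leaf)
                pruned += 1
    return pruned


def prune_uninvolved_labels(tree: MULTree) -> MULTree:
    """Prune every leaf whose label appears in no resolved quartet of the
    current tree.  A tree with empty information content reduces to the empty
    tree."""
    out = tree.copy()
    _prune_uninvolved_inplace(out)
    out.validate()
    return out


def _dedupe_sibling_inplace(tree: MULTree) -> int:
    pruned = 0
    for p in tree.pendant_nodes():
        if p not in tree.graph:
            continue
        by_label: Dict[str, List[int]] = {}
        for nb in tree.neighbors(p):
            if nb in tree.leaf_label:
                by_label.setdefault(tree.leaf_label[nb], []).append(nb)
        for label, leaves in sorted(by_label.items()):
            for leaf in sorted(leaves)[1:]:
                tree.prune_leaf_inplace(leaf)
                pruned += 1
    return pruned


def dedupe_sibling_leaves(tree: MULTree) -> MULTree:
    """At every pendant node, keep only one leaf per label (the first in
    node order)."""
    out = tree.copy()
    _dedupe_sibling_inplace(out)
    out.validate()
    return out


def _spanning_degrees(
    tree: MULTree, leaves: List[int]
) -> Dict[int, int]:
    """Degree of each node within the minimal subtree spanning ``leaves``."""
    g = tree.graph
    root = leaves[0]
    targets = set(leaves)
    parent: Dict[int, Optional[int]] = {root: None}
    order = [root]
    for node in order:
        for nb in g.neighbors(node):
            if nb not in parent:
                parent[nb] = node
                order.append(nb)
    down: Dict[int, int] = {}
    for node in reversed(order):
        cnt = 1 if node in targets else 0
        for nb in g.neighbors(node):
            if nb != parent[node]:
                cnt += down[nb]
        down[node] = cnt
    deg: Dict[int, int] = {}
    for node in order[1:]:
        if down[node] >= 1:  # edge (parent, node) lies on a spanning path
            p = parent[node]
            deg[p] = deg.get(p, 0) + 1
            deg[node] = deg.get(node, 0) + 1
    return deg


def _prune_spanning_inplace(tree: MULTree) -> int:
    pruned = 0
    for label in sorted(tree.labels()):
        while True:
            leaves = tree.leaves_with_label(label)
            if len(leaves) < 2:
                break
            deg = _spanning_degrees(tree, leaves)
            victim = None
            for leaf in leaves:
                pendant = next(iter(tree.graph.neighbors(leaf)))
                if deg.get(pendant, 0) >= 3:
                    victim = leaf
                    break
            if victim is None:
                break
            tree.prune_leaf_inplace(victim)
            pruned += 1
    return pruned


def prune_spanning_redundant(tree: MULTree) -> MULTree:
    """For each multiply-occurring label, prune copies attached at nodes of
    degree >= 3 within the label's minimal spanning subtree (such copies lie
    strictly between other copies and resolve nothing of their own).

    Assumes same-labeled leaves sharing a pendant node were deduplicated
    first."""
    out = tree.copy()
    _prune_spanning_inplace(out)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# The full reduction
# ---------------------------------------------------------------------------


def mrf(
    tree: MULTree, debug: bool = False
) -> Tuple[MULTree, ReductionReport]:
    """Reduce a normalized MUL-tree to its maximally reduced form.

    The three-phase pipeline is repeated until a full pass changes nothing,
    so the result is a verified fixed point of all five reduction rules.
    With ``debug=True`` the fixed point is additionally certified the
    expensive way: every single prune/contract is tried and must change the
    (brute-force) information content — only feasible for small trees.

    Returns the MRF together with a :class:`ReductionReport`.  The MRF of a
    tree that resolves no conflict-free quartet is the empty tree, with
    ``no_information`` set so callers may keep the original instead.
    """
    work = tree.copy()
    report = ReductionReport()
    input_labels = tree.labels()
    while True:
        changed = False
        c1 = _contract_uninformative_inplace(work)
        report.phase1_contractions += c1
        changed |= c1 > 0
        changed |= _contract_subsumed_inplace(work, report)
        p_unv = _prune_uninvolved_inplace(work)
        report.leaves_pruned["no_quartet_label"] += p_unv
        changed |= p_unv > 0
        p_ded = _dedupe_sibling_inplace(work)
        report.leaves_pruned["pendant_dedupe"] += p_ded
        changed |= p_ded > 0
        p_span = _prune_spanning_inplace(work)
        report.leaves_pruned["spanning_rule"] += p_span
        changed |= p_span > 0
        if not changed:
            break
    work.validate()
    report.no_information = work.is_empty()
    if input_labels:
        lost = len(input_labels) - len(work.labels())
        report.taxa_lost_step1_pct = 100.0 * lost / len(input_labels)
    if debug:
        _assert_irreducible(work)
    return work, report


def _assert_irreducible(tree: MULTree) -> None:
    """Certify by brute force that no single edit preserves I (debug aid)."""
    base = information_content(tree)
    for leaf in tree.leaves():
        cand = tree.copy()
        cand.prune_leaf_inplace(leaf)
        if information_content(cand) == base:
            raise RuntimeError(
                f"leaf {leaf} ({tree.leaf_label[leaf]!r}) is still prunable"
            )
    for u, v in tree.internal_edges():
        cand = tree.copy()
        cand.contract_edge_inplace(u, v)
        if information_content(cand) == base:
            raise RuntimeError(f"edge ({u}, {v}) is still contractible")


def reference_mrf(
    tree: MULTree, seed: int = 0, max_leaves: int = 15
) -> MULTree:
    """Brute-force oracle reducer: apply, in a seeded random order, any
    edit that leaves the brute-force information content unchanged, until
    none applies.

    The candidate edits are single leaf prunes, single internal edge
    contractions, and whole-label deletions (all leaves of one label at
    once).  The whole-label move is needed for confluence: duplicate copies
    of a label that participates in no quartet shield each other — pruning
    one copy alone *adds* quartets by making the surviving copy exclusive —
    yet deleting the label entirely is information-preserving.

    Exponentially slower than :func:`mrf` (I is recomputed per candidate
    edit) and guarded to small trees; by the uniqueness of the MRF the result
    is isomorphic to ``mrf(tree)[0]`` regardless of the seed.
    """
    if tree.n_leaves() > max_leaves:
        raise ValueError(
            f"reference reducer is limited to {max_leaves} leaves"
        )
    rng = random.Random(seed)
    work = tree.copy()
    target = information_content(work)
    while True:
        ops: List[Tuple[str, object]] = [
            ("prune", leaf) for leaf in work.leaves()
        ]
        ops += [("contract", e) for e in work.internal_edges()]
        ops += [("drop_label", lab) for lab in sorted(work.labels())]
        rng.shuffle(ops)
        applied = False
        for kind, arg in ops:
            cand = work.copy()
            if kind == "prune":
                cand.prune_leaf_inplace(arg)  # type: ignore[arg-type]
            elif kind == "contract":
                cand.contract_edge_inplace(*arg)  # type: ignore[misc]
            else:
                for leaf in cand.leaves_with_label(arg):  # type: ignore[arg-type]
                    cand.prune_leaf_inplace(leaf)
            if information_content(cand) == target:
                work = cand
                applied = True
                break
        if not applied:
            break
    return work


def restrict_to_unique_labels(tree: MULTree) -> MULTree:
    """Second-step restriction: delete every leaf whose label occurs more
    than once, leaving a singly-labeled (possibly empty) tree.

    Quartets may be lost, never invented: the result displays no topology on
    surviving labels that conflicts with the input's information content.
    Edges left uninformative by the deletions are contracted so the emitted
    tree is clean."""
    out = tree.copy()
    mult = out.label_multiplicity()
    for leaf, label in sorted(list(out.leaf_label.items())):
        if mult[label] >= 2 and leaf in out.leaf_label:
            out.prune_leaf_inplace(leaf)
    while _contract_uninformative_inplace(out):
        pass
    out.validate()
    return out


def reduce_two_step(
    tree: MULTree, debug: bool = False
) -> Tuple[MULTree, MULTree, ReductionReport]:
    """Run the full two-step program: MRF, then restriction to once-occurring
    labels.  Returns (mrf_tree, restricted_tree, report) with both taxon-loss
    percentages filled in."""
    mrf_tree, report = mrf(tree, debug=debug)
    restricted = restrict_to_unique_labels(mrf_tree)
    input_labels = tree.labels()
    if input_labels:
        lost = len(input_labels) - len(restricted.labels())
        report.taxa_lost_step2_pct = 100.0 * lost / len(input_labels)
    else:
        report.taxa_lost_step2_pct = 0.0
    return mrf_tree, restricted, report
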