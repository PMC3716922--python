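"""The three-phase MRF reduction, its oracle, and the restriction step."""

import pytest

from mulred import (
    EQUAL,
    INCOMPARABLE,
    INNER_SUBSET,
    OUTER_SUBSET,
    MULTree,
    StaleCountsError,
    all_partition_counts,
    contract_subsumed,
    contract_uninformative,
    dedupe_sibling_leaves,
    delta,
    edge_subsumption,
    information_content,
    is_isomorphic,
    mrf,
    parse_newick,
    prune_spanning_redundant,
    prune_uninvolved_labels,
    reduce_two_step,
    reference_mrf,
    restrict_to_unique_labels,
    search_irreducible,
)

from conftest import make_random_tree, make_small_tree
from test_core import pendant_of


def build(branches):
    """Pendant nodes, each bearing the given leaves: two of them joined by an
    edge, more arranged around a hub."""
    tree = MULTree()
    pendants = []
    for labs in branches:
        node = tree.new_node()
        pendants.append(node)
        for lab in labs:
            tree.add_edge(node, tree.new_node(lab))
    if len(pendants) == 2:
        tree.add_edge(*pendants)
    else:
        hub = tree.new_node()
        for node in pendants:
            tree.add_edge(hub, node)
    tree.validate()
    return tree


# ---------------------------------------------------------------------------
# phase 1: uninformative edges
# ---------------------------------------------------------------------------


def test_phase1_contracts_fixture_vw(demo_tree):
    out = contract_uninformative(demo_tree)
    # (v,w) has exclusive side {d}; the other two internal edges stay
    assert len(out.internal_edges()) == 2
    assert information_content(out) == information_content(demo_tree)


def test_phase1_keeps_informative_singly_tree():
    (tree,) = parse_newick("((a,b),(c,d),(e,f));")
    out = contract_uninformative(tree)
    assert is_isomorphic(out, tree)


def test_phase1_star_unchanged():
    (star,) = parse_newick("(a,b,c,d);")
    assert is_isomorphic(contract_uninformative(star), star)


# ---------------------------------------------------------------------------
# edge subsumption relation
# ---------------------------------------------------------------------------


def test_subsumption_edge_vs_itself(demo_tree):
    counts = all_partition_counts(demo_tree)
    edge = demo_tree.internal_edges()[0]
    assert edge_subsumption(demo_tree, counts, edge, edge) == EQUAL


def test_subsumption_matches_bruteforce_deltas():
    for seed in range(25):
        tree = make_random_tree(seed, max_labels=8, max_extra=6)
        counts = all_partition_counts(tree)
        internal = tree.internal_edges()
        for i in range(len(internal)):
            for j in range(i + 1, len(internal)):
                e1, e2 = internal[i], internal[j]
                rel = edge_subsumption(tree, counts, e1, e2)
                d1, d2 = delta(tree, e1), delta(tree, e2)
                if rel == EQUAL:
                    assert d1 == d2
                elif rel == INNER_SUBSET:
                    assert d1 <= d2
                elif rel == OUTER_SUBSET:
                    assert d2 <= d1
                elif d1 and d2:
                    # the cardinality criterion characterizes subsets only
                    # for informative edges (empty deltas nest trivially)
                    assert not (d1 <= d2) and not (d2 <= d1)


def test_subsumption_incomparable_on_singly_caterpillar():
    (tree,) = parse_newick("(a,b,(c,(d,(e,f))));")
    counts = all_partition_counts(tree)
    internal = tree.internal_edges()
    for i in range(len(internal)):
        for j in range(i + 1, len(internal)):
            assert (
                edge_subsumption(tree, counts, internal[i], internal[j])
                == INCOMPARABLE
            )


def test_subsumption_requires_fresh_counts(demo_tree):
    counts = all_partition_counts(demo_tree)
    edge = demo_tree.internal_edges()[0]
    demo_tree.prune_leaf_inplace(demo_tree.leaves()[0])
    with pytest.raises(StaleCountsError):
        edge_subsumption(demo_tree, counts, edge, edge)


# ---------------------------------------------------------------------------
# phase 2: subsumed edges, branching subtrees
# ---------------------------------------------------------------------------


def test_phase2_fixture_single_internal_edge(demo_tree):
    out = contract_subsumed(contract_uninformative(demo_tree))
    assert len(out.internal_edges()) == 1
    assert information_content(out) == information_content(demo_tree)


def test_phase2_deletes_branch_when_deltas_equal():
    # path u-v-w with the same label e on both ends: Delta(u,v) = Delta(v,w)
    # = {ab|cd}; the leaf branching off v carries no information and the
    # whole branch is deleted
    tree = MULTree()
    u, v, w = (tree.new_node() for _ in range(3))
    tree.add_edge(u, v)
    tree.add_edge(v, w)
    for node, labs in ((u, ["a", "b", "e"]), (v, ["e"]), (w, ["c", "d", "e"])):
        for lab in labs:
            tree.add_edge(node, tree.new_node(lab))
    tree.validate()
    before = information_content(tree)
    out = contract_subsumed(tree)
    assert information_content(out) == before
    assert out.label_multiplicity()["e"] == 2
    assert len(out.internal_edges()) == 1


def test_phase2_no_change_when_incomparable():
    (tree,) = parse_newick("((a,b),(c,d),(e,f));")
    assert is_isomorphic(contract_subsumed(tree), tree)


# ---------------------------------------------------------------------------
# phase 3: leaf pruning rules
# ---------------------------------------------------------------------------


def test_prune_label_common_everywhere():
    # f sits on both sides of the only informative edge and in no exclusive
    # set of any edge: both copies go, I unchanged
    tree = build(["abf", "cdf"])
    before = information_content(tree)
    out = prune_uninvolved_labels(tree)
    assert "f" not in out.labels()
    assert information_content(out) == before


def test_prune_uninvolved_empties_zero_information_tree():
    (star,) = parse_newick("(a,b,c,d);")
    assert prune_uninvolved_labels(star).is_empty()


def test_dedupe_sibling_leaves():
    tree = build(["aaab", "cd"])
    out = dedupe_sibling_leaves(tree)
    assert sorted(out.leaf_label.values()) == ["a", "b", "c", "d"]
    (singly,) = parse_newick("((a,b),(c,d));")
    assert is_isomorphic(dedupe_sibling_leaves(singly), singly)


def test_spanning_rule_prunes_interior_copy():
    # label x at three pendant nodes along a path; the middle pendant node
    # has degree three in x's spanning subtree, so its copy goes
    tree = MULTree()
    u, v, y = (tree.new_node() for _ in range(3))
    tree.add_edge(u, v)
    tree.add_edge(v, y)
    for node, labs in ((u, ["x", "p", "q"]), (v, ["x", "r"]), (y, ["x", "s", "t"])):
        for lab in labs:
            tree.add_edge(node, tree.new_node(lab))
    tree.validate()
    before = information_content(tree)
    out = prune_spanning_redundant(tree)
    assert out.label_multiplicity()["x"] == 2
    # the copy at the interior pendant node v (the one with leaf r) is gone
    assert "x" not in [
        out.leaf_label[nb]
        for nb in out.neighbors(pendant_of(out, ["r"]))
        if nb in out.leaf_label
    ]
    assert information_content(out) == before


def test_spanning_rule_keeps_two_copies():
    tree = build(["xab", "xcd"])
    assert is_isomorphic(prune_spanning_redundant(tree), tree)


@pytest.mark.parametrize("seed", range(15))
def test_spanning_rule_idempotent(seed):
    tree = make_random_tree(seed, max_labels=8, max_extra=8)
    once = prune_spanning_redundant(dedupe_sibling_leaves(tree))
    again = prune_spanning_redundant(once)
    assert is_isomorphic(once, again)


# ---------------------------------------------------------------------------
# the full reduction
# ---------------------------------------------------------------------------


def test_mrf_fixture(demo_tree):
    reduced, report = mrf(demo_tree, debug=True)
    assert reduced.n_leaves() == 6
    assert max(reduced.label_multiplicity().values()) == 1
    assert len(reduced.internal_edges()) == 1
    u, v = reduced.internal_edges()[0]
    from mulred import edge_partition

    part = edge_partition(reduced, (u, v))
    assert {part.m_u, part.m_v} == {
        frozenset({"a", "f"}),
        frozenset({"b", "c", "d", "e"}),
    }
    assert len(information_content(reduced)) == 6
    assert information_content(reduced) == information_content(demo_tree)
    assert not report.no_information
    assert report.taxa_lost_step1_pct == 0.0


def test_mrf_star_is_empty_with_flag():
    (star,) = parse_newick("(a,b,c,d);")
    reduced, report = mrf(star)
    assert reduced.is_empty()
    assert report.no_information
    assert report.taxa_lost_step1_pct == 100.0


@pytest.mark.parametrize("seed", range(30))
def test_mrf_preserves_information(seed):
    tree = make_random_tree(seed)
    reduced, _ = mrf(tree)
    assert information_content(reduced) == information_content(tree)


@pytest.mark.parametrize("seed", range(20))
def test_mrf_agrees_with_reference(seed):
    tree = make_small_tree(seed)
    reduced, _ = mrf(tree, debug=True)
    assert is_isomorphic(reduced, reference_mrf(tree, seed=seed + 1))


@pytest.mark.parametrize("seed", range(15))
def test_mrf_idempotent(seed):
    tree = make_random_tree(seed)
    reduced, _ = mrf(tree)
    again, report = mrf(reduced)
    assert is_isomorphic(reduced, again)
    assert report.taxa_lost_step1_pct == 0.0


def test_reference_order_independence():
    tree = make_small_tree(5)
    results = [reference_mrf(tree, seed=s) for s in range(4)]
    assert all(is_isomorphic(results[0], r) for r in results[1:])


def test_reference_fixed_point(demo_tree):
    reduced, _ = mrf(demo_tree)
    assert is_isomorphic(reference_mrf(reduced, seed=9), reduced)


def test_reference_size_guard():
    from mulred import GeneratorConfig, random_multree

    tree = random_multree(GeneratorConfig(16, 0, seed=1))
    with pytest.raises(ValueError):
        reference_mrf(tree)


@pytest.mark.parametrize("seed", range(15))
def test_singly_binary_trees_are_their_own_mrf(seed):
    tree = make_random_tree(seed, min_labels=4, max_labels=12, max_extra=0)
    reduced, report = mrf(tree)
    assert is_isomorphic(reduced, tree)
    assert report.taxa_lost_step1_pct == 0.0


# ---------------------------------------------------------------------------
# restriction to once-occurring labels
# ---------------------------------------------------------------------------


def test_restrict_singly_mrf_unchanged(demo_tree):
    reduced, _ = mrf(demo_tree)
    assert is_isomorphic(restrict_to_unique_labels(reduced), reduced)


def test_restrict_all_duplicated_is_empty():
    (tree,) = parse_newick("((a,b),(a,b));")
    assert restrict_to_unique_labels(tree).is_empty()


def test_irreducible_witness_loses_quartets():
    """A multi-labeled MRF cannot be restricted to a singly-labeled tree
    with the same information content."""
    witness = search_irreducible(7, 3, range(200))
    assert witness is not None
    reduced, _ = mrf(witness)
    assert is_isomorphic(reduced, witness)  # it is its own MRF
    assert max(witness.label_multiplicity().values()) >= 2
    restricted = restrict_to_unique_labels(witness)
    lost = information_content(witness) - information_content(restricted)
    assert lost  # strict loss (proper containment the other way is banned)
    # relabeling instead gives a singly-labeled tree with strictly MORE info
    from mulred import relabel_to_singly

    relabeled = relabel_to_singly(witness)
    assert information_content(witness) < information_content(relabeled)


@pytest.mark.parametrize("seed", range(20))
def test_restriction_is_conservative(seed):
    """Restriction loses quartets but never invents a topology conflicting
    with the MRF's information content."""
    tree = make_random_tree(seed)
    reduced, _ = mrf(tree)
    restricted = restrict_to_unique_labels(reduced)
    base = {q.support: q for q in information_content(reduced)}
    for quartet in information_content(restricted):
        assert base.get(quartet.support, quartet) == quartet


def test_two_step_report_fields(demo_tree):
    mrf_tree, restricted, report = reduce_two_step(demo_tree)
    d = report.to_dict()
    assert d["taxaLostStep1"] == 0.0
    assert d["taxaLostStep2"] == 0.0
    assert 0 <= d["taxaLostStep1"] <= 100
    assert d["noInformation"] is False
    assert d["leavesPruned"]["pendantDedupe"] == 2
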