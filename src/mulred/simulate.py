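"""Seeded synthetic MUL-trees, a worked in-memory fixture, and corpus-level
statistics for the two-step reduction pipeline.

The generator grows a random binary tree on a set of unique taxon labels and
then scatters extra leaf copies of randomly chosen existing labels onto
randomly chosen edges.  This emulates the structural phenomenon that makes
MUL-trees hard to use directly — the same taxon appearing at several places
in the tree — without modeling any particular biological process (gene
duplication, lineage sorting, annotation error) that produces it in
empirical gene-family trees.

:func:`corpus_summary` mirrors the bookkeeping of a two-step reduction
experiment over a corpus: per-tree taxon losses for the MRF step and for the
restriction to once-occurring labels, the fraction of trees whose MRF is
already singly labeled, the fraction only the restriction step makes singly
labeled, the fraction with no usable information, and the loss of the naive
alternative that simply removes every multiply-occurring taxon up front.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .core import MULTree, normalize, write_newick
from .quartets import information_content
from .reduce import reduce_two_step

__all__ = [
    "GeneratorConfig",
    "CorpusStats",
    "random_multree",
    "conflict_example_tree",
    "search_irreducible",
    "corpus_summary",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of one synthetic MUL-tree.

    ``n_labels`` unique taxa (>= 4) are placed on a random binary topology;
    ``n_extra_copies`` additional leaves, each a duplicate of a uniformly
    chosen existing label, are attached to uniformly chosen edges.  The same
    config always yields the byte-identical Newick string.
    """

    n_labels: int
    n_extra_copies: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_labels < 4:
            raise ValueError("need at least 4 distinct labels")
        if self.n_extra_copies < 0:
            raise ValueError("n_extra_copies must be >= 0")


def random_multree(config: GeneratorConfig) -> MULTree:
    """Generate a seeded random MUL-tree; leaf count is
    ``n_labels + n_extra_copies``."""
    rng = random.Random(config.seed)
    labels = [f"t{i + 1}" for i in range(config.n_labels)]
    tree = MULTree()
    # start from the 3-leaf star, then attach remaining leaves by edge
    # subdivision (uniform random binary topology growth)
    hub = tree.new_node()
    for lab in labels[:3]:
        tree.add_edge(hub, tree.new_node(lab))
    for lab in labels[3:]:
        _attach_leaf(tree, rng, lab)
    for _ in range(config.n_extra_copies):
        lab = rng.choice(labels)
        _attach_leaf(tree, rng, lab)
    tree.validate()
    return tree


def _attach_leaf(tree: MULTree, rng: random.Random, label: str) -> None:
    u, v = rng.choice(tree.edges())
    mid = tree.new_node()
    leaf = tree.new_node(label)
    tree.graph.remove_edge(u, v)
    tree.add_edge(u, mid)
    tree.add_edge(mid, v)
    tree.add_edge(mid, leaf)


def conflict_example_tree() -> MULTree:
    """A small MUL-tree with an internal path t-u-v-w where taxa b and c each
    label two leaves.

    Node t bears leaves a, f; u bears the first copies of b and c; v bears
    the second copy of c and e; w bears the second copy of b and d.  The
    label copies put conflicting topologies on {b, c, d, e} (bc|de across
    (u,v) leafwise, bd|ce across (v,w)), while edge (u,v) formally resolves
    exactly af|de and edge (t,u) resolves the six conflict-free quartets
    pairing {a, f} against {b, c, d, e}.  Its MRF is the singly-labeled
    6-leaf tree with the single internal edge af | bcde.
    """
    tree = MULTree()
    t = tree.new_node()
    u = tree.new_node()
    v = tree.new_node()
    w = tree.new_node()
    tree.add_edge(t, u)
    tree.add_edge(u, v)
    tree.add_edge(v, w)
    for node, labs in ((t, "af"), (u, "bc"), (v, "ce"), (w, "bd")):
        for lab in labs:
            tree.add_edge(node, tree.new_node(lab))
    tree.validate()
    return tree


def search_irreducible(
    max_labels: int = 7,
    max_extra: int = 3,
    seed_range: Iterable[int] = range(10000),
) -> Optional[MULTree]:
    """Search the generator space for a maximally reduced tree that is still
    multi-labeled.

    Such trees witness that MUL-trees are strictly more expressive than
    singly-labeled trees: no singly-labeled tree has exactly their
    information content, so restricting them to once-occurring labels must
    lose quartets.  All label counts 4..max_labels and duplication counts
    1..max_extra are tried for each seed; the smallest witnesses need about
    seven distinct labels (two exclusive pairs flanking the duplicated taxon,
    plus a separated pair to pair it with), so smaller bounds may search
    forever.  Returns the (multi-labeled) MRF of the first generated tree
    whose MRF keeps a label at multiplicity >= 2, or None."""
    from .reduce import mrf  # local import to avoid cycle at module load

    for seed in seed_range:
        for n_labels in range(4, max_labels + 1):
            for n_extra in range(1, max_extra + 1):
                config = GeneratorConfig(
                    n_labels=n_labels, n_extra_copies=n_extra, seed=seed
                )
                tree = random_multree(config)
                reduced, _ = mrf(tree)
                if reduced.is_empty():
                    continue
                if max(reduced.label_multiplicity().values()) >= 2:
                    return reduced
    return None


@dataclass
class CorpusStats:
    """Aggregate statistics of the two-step pipeline over a corpus.

    Fractions: ``frac_no_information`` (empty MRF or empty restriction),
    ``frac_singly_labeled_mrf`` (set A: step 1 alone yields a singly-labeled
    tree), ``frac_restricted_in_step2`` (set B: restriction had to remove
    leaves).  Mean losses are percentages of distinct input taxa;
    ``mean_taxon_loss_step2`` averages over set B (the trees the second step
    actually restricts), ``mean_naive_loss`` is the loss of dropping every
    MUL-taxon up front, averaged over all trees."""

    n_trees: int = 0
    frac_no_information: float = 0.0
    frac_singly_labeled_mrf: float = 0.0
    frac_restricted_in_step2: float = 0.0
    mean_taxon_loss_step1: float = 0.0
    mean_taxon_loss_step2: float = 0.0
    mean_naive_loss: float = 0.0
    node_counts: List[Dict[str, int]] = field(default_factory=list)
    per_tree: List[Dict[str, object]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "nTrees": self.n_trees,
            "fracNoInformation": self.frac_no_information,
            "fracSinglyLabeledMRF": self.frac_singly_labeled_mrf,
            "fracRestrictedInStep2": self.frac_restricted_in_step2,
            "meanTaxonLossStep1": self.mean_taxon_loss_step1,
            "meanTaxonLossStep2": self.mean_taxon_loss_step2,
            "meanNaiveLoss": self.mean_naive_loss,
            "nodeCounts": self.node_counts,
        }

    TSV_COLUMNS = (
        "tree",
        "leaves",
        "distinct_labels",
        "mrf_leaves",
        "restricted_leaves",
        "loss_step1_pct",
        "loss_step2_pct",
        "naive_loss_pct",
        "category",
    )

    def to_tsv(self) -> str:
        lines = ["\t".join(self.TSV_COLUMNS)]
        for row in self.per_tree:
            lines.append(
                "\t".join(str(row[col]) for col in self.TSV_COLUMNS)
            )
        return "\n".join(lines) + "\n"


def corpus_summary(trees: Sequence[MULTree]) -> CorpusStats:
    """Run the two-step reduction over every tree and aggregate the
    bookkeeping; deterministic given the corpus, order-invariant in the
    aggregates."""
    trees = list(trees)
    if not trees:
        raise ValueError("empty corpus")
    stats = CorpusStats(n_trees=len(trees))
    n_no_info = n_set_a = n_set_b = 0
    losses1: List[float] = []
    losses2_set_b: List[float] = []
    naive: List[float] = []
    for idx, tree in enumerate(trees):
        mrf_tree, restricted, report = reduce_two_step(tree)
        n_in = len(tree.labels())
        mult = tree.label_multiplicity()
        n_mul = sum(1 for c in mult.values() if c >= 2)
        naive_loss = 100.0 * n_mul / n_in if n_in else 0.0
        if mrf_tree.is_empty() or restricted.is_empty():
            category = "no_information"
            n_no_info += 1
        elif max(mrf_tree.label_multiplicity().values()) == 1:
            category = "A"
            n_set_a += 1
        else:
            category = "B"
            n_set_b += 1
            losses2_set_b.append(report.taxa_lost_step2_pct)
        losses1.append(report.taxa_lost_step1_pct)
        naive.append(naive_loss)
        stats.node_counts.append(
            {
                "input": tree.graph.number_of_nodes(),
                "mrf": mrf_tree.graph.number_of_nodes(),
                "restricted": restricted.graph.number_of_nodes(),
            }
        )
        stats.per_tree.append(
            {
                "tree": idx,
                "leaves": tree.n_leaves(),
                "distinct_labels": n_in,
                "mrf_leaves": mrf_tree.n_leaves(),
                "restricted_leaves": restricted.n_leaves(),
                "loss_step1_pct": round(report.taxa_lost_step1_pct, 4),
                "loss_step2_pct": round(report.taxa_lost_step2_pct, 4),
                "naive_loss_pct": round(naive_loss, 4),
                "category": category,
            }
        )
    n = len(trees)
    stats.frac_no_information = n_no_info / n
    stats.frac_singly_labeled_mrf = n_set_a / n
    stats.frac_restricted_in_step2 = n_set_b / n
    stats.mean_taxon_loss_step1 = sum(losses1) / n
    stats.mean_taxon_loss_step2 = (
        sum(losses2_set_b) / len(losses2_set_b) if losses2_set_b else 0.0
    )
    stats.mean_naive_loss = sum(naive) / n
    return stats
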