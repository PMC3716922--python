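# Methods

## Model

A MUL-tree is a triple (*T*, *M*, ψ): an unrooted tree *T* whose internal
nodes have degree ≥ 3, a label set *M*, and a surjective map ψ from leaves to
labels. Singly-labeled trees are the special case where ψ is a bijection.
Only topology and ψ matter; branch lengths, support values and internal node
names are parsed and discarded. Rooted inputs are unrooted by suppressing
the degree-2 root.

For an edge (*u*,*v*), deleting the edge splits the leaves into two sides;
*M<sub>u</sub>* and *M<sub>v</sub>* are the labels exclusive to each side and
*C* the labels with copies on both sides; the three sets partition *M*. The
edge resolves quartet *ab*|*cd* when *a*,*b* ∈ *M<sub>u</sub>* and *c*,*d* ∈
*M<sub>v</sub>* — labels in *C* resolve nothing, which is exactly how
conflicting placements are excluded. The information content I(*T*) is the
union of the per-edge quartet sets; it is conflict-free and is displayed by
at least one singly-labeled tree (relabel all duplicate copies with fresh
names; `relabel_to_singly` implements this construction, keeping the
first-encountered copy in a deterministic DFS).

A leaf is prunable / an internal edge contractible when the edit leaves
I(*T*) unchanged; the maximally reduced form (MRF) is the fixed point of
these edits, and it is unique, which the test suite exercises rather than
assumes (isomorphism between the production reducer and a brute-force
reference reducer under many shuffled edit orders).

## The reducer

`mrf` runs three phases over per-edge *exclusive-label counts* and repeats
the whole pipeline until a pass changes nothing:

1. **Uninformative edges.** Internal edges where either exclusive side has
   ≤ 1 label are contracted. Contraction never changes another edge's
   bipartition, so one batch runs under one set of counts.
2. **Subsumed edges.** For adjacent internal edges (*u*,*v*), (*v*,*w*) the
   quartet sets nest exactly when the far-side exclusive counts agree, and
   coincide when the near-side counts agree as well (the far/near sets are
   nested, so cardinality equality is set equality). On a hit, the less
   informative edge is contracted and the internal edges of subtrees
   branching off *v* are collapsed; when the two quartet sets are *equal*,
   those branching subtrees carry no information of their own and are
   deleted outright. The scan restarts with fresh counts after each event.
3. **Redundant leaves.** (a) Every leaf whose label occurs in no exclusive
   set of any informative edge — i.e. participates in no resolved quartet —
   is pruned, label by label. (b) Same-labeled leaves sharing a pendant node
   are deduplicated to one copy. (c) For each remaining multiply-occurring
   label, within the minimal subtree spanning its leaves, copies attached at
   nodes of spanning-degree ≥ 3 lie strictly between other copies and are
   pruned; the two "outermost" copies always survive.

Counts are bitmask-packed (one bit per label, two tree traversals per
recomputation) and recomputed per phase / per phase-2 event rather than
maintained incrementally — the same asymptotic budget, much less machinery.
Empirically the reduction is near-quadratic: the acceptance script measures
a log-log slope of ~2.1–2.2 over 250/500/1000-leaf trees, with a 1000-leaf
reduction taking ~2 s on one CPU.

### Fixed point, not faith

The three phases are believed sufficient, but `mrf` does not rely on that:
the pipeline loops until a full pass is a no-op, so an implementation gap
degrades to wasted sweeps, never to wrong output. `mrf(..., debug=True)`
additionally certifies irreducibility by brute force (every single edit must
change I), which is feasible only at test sizes.

### A confluence trap worth knowing

The single-edit greedy definition has reachable stuck states: if a label
that participates in *no* quartet has two or more copies, pruning one copy
alone *adds* quartets (the surviving copy becomes side-exclusive), so no
single edit preserves I — yet deleting the label entirely is
information-preserving, and phase 3(a) does exactly that. The brute-force
`reference_mrf` therefore includes atomic whole-label deletion among its
candidate edits (still accepted purely by I-equality); without it,
order-independence demonstrably fails. Uniqueness of the MRF holds for the
edit system that includes this move, and is what the multi-seed agreement
tests certify.

## Restriction to once-occurring labels

`restrict_to_unique_labels` deletes every leaf of a multiply-occurring label
from the MRF and re-contracts edges left uninformative. The result is
singly labeled (possibly empty). It can lose quartets — necessarily so when
the MRF is itself multi-labeled (`search_irreducible` finds such witnesses;
the smallest need ~7 distinct labels: two exclusive pairs flanking the
duplicated taxon plus a separated pair for it to quartet with) — but it
never introduces a topology on surviving labels that conflicts with the
MRF's information content.

## Degenerate inputs

Trees with fewer than four distinct labels, or with empty I (stars, heavily
duplicated small trees), reduce to the **empty tree**; the report's
`noInformation` flag is set so callers can keep the original. This is the
strict fixed point of the definitions; the empty tree is first-class
throughout (`write_newick` emits `;`).

## Tunable parameters

- `GeneratorConfig(n_labels, n_extra_copies, seed)` — the synthetic
  generator grows a uniform random binary topology on `n_labels` unique taxa
  (sequential edge subdivision) and then attaches `n_extra_copies` duplicate
  leaves, each a uniformly chosen existing label on a uniformly chosen edge.
  Test corpora draw 4–12 labels and 0–10 extra copies per tree: small enough
  that brute-force quartet oracles stay exact, duplicated enough that every
  reduction rule fires. The generator emulates only the structural
  phenomenon (scattered duplicate labels); it does not model gene-family
  evolution, so corpus-level fractions and losses here say nothing
  quantitative about empirical databases — only the universal properties
  (information preservation, uniqueness, conservativeness) transfer.
- `reference_mrf(tree, seed, max_leaves=15)` — oracle cost guard; I is
  recomputed per candidate edit.
- `relabel_to_singly(..., keep_policy="first-dfs")` — fresh names are
  `label#2`, `label#3`, … in traversal order; a collision with an existing
  label raises.

## Corpus accounting

`corpus_summary` classifies each tree: `no_information` (empty MRF or empty
restriction), `A` (MRF already singly labeled), `B` (restriction removed
leaves). Taxon loss is measured on distinct labels, not leaf copies:
step 1 loss is labels absent from the MRF (all mean-step-1 percentages
average over all trees), step 2 loss is labels absent after restriction
(averaged over set B, the trees the step actually touches), and the naive
baseline is the fraction of MUL-taxa (what deleting every duplicated taxon
up front would cost). For every tree with nonempty information content the
two-step loss is ≤ the naive loss — each taxon it loses is a MUL-taxon —
whereas zero-information trees lose everything by definition and are
reported in their own category.

## Numerical / determinism choices

- Canonical form: the tree is rooted at its centroid (or the midpoint of the
  centroid edge) and subtree signatures are sorted recursively; leaf
  signatures are JSON-escaped labels. Equal strings ⇔ isomorphic as
  unrooted leaf-label-multiset trees. Isomorphism testing is string
  comparison of canonical forms.
- All randomness (generator, reference-reducer shuffles) flows through
  explicit integer seeds; the same seed reproduces byte-identical Newick and
  JSON outputs.
- Labels are whitespace-normalized (internal whitespace → `_`) at parse
  time; comparison is exact text equality.
- Tie-breaks (which duplicate survives deduplication, DFS orders) follow
  node-id order — irrelevant to the isomorphism class of any result, which
  the order-independence tests confirm.

## Known limitations

- Quartet sets are materialized explicitly (O(|M|⁴) in the worst case);
  `information_content` and everything downstream of it is an oracle for
  moderate label counts, not a production path — the reducer itself never
  materializes I.
- The rooted/triplet analogue of the theory is not implemented.
- `conflicting_label_sets` implements a leafwise-display reading of
  "conflicting quartets" (an edge displays ab|cd leafwise when leaves so
  labeled lie on opposite sides, duplicates free to be reused); it is a
  diagnostic, deliberately quarantined from the core guarantees.
- Polytomies are preserved, never refined; two MUL-trees are compared only
  up to MRF isomorphism.
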