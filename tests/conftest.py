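import random

import pytest

from mulred import GeneratorConfig, conflict_example_tree, random_multree


def make_random_tree(seed, min_labels=4, max_labels=12, max_extra=10):
    """Seeded random MUL-tree with label/duplication counts drawn from the
    given ranges (one derived stream per seed)."""
    rng = random.Random(seed)
    config = GeneratorConfig(
        n_labels=rng.randint(min_labels, max_labels),
        n_extra_copies=rng.randint(0, max_extra),
        seed=rng.randrange(2**31),
    )
    return random_multree(config)


def make_small_tree(seed, max_leaves=10):
    """Random MUL-tree capped at ``max_leaves`` (for brute-force oracles)."""
    rng = random.Random(seed)
    while True:
        n_labels = rng.randint(4, 7)
        n_extra = rng.randint(0, max_leaves - n_labels)
        tree = random_multree(
            GeneratorConfig(n_labels, n_extra, seed=rng.randrange(2**31))
        )
        if tree.n_leaves() <= max_leaves:
            return tree


@pytest.fixture
def demo_tree():
    return conflict_example_tree()
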