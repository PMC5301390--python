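"""Shared tree-generation helpers for the test suite.

All fixtures are generated programmatically; nothing is read from disk.
"""

from __future__ import annotations

import numpy as np
import pytest

# ---------------------------------------------------------------------------
# unrooted binary topology enumeration / random generation
#
# Trees are built as nested structures: a leaf is a label string, an
# internal node a tuple of children.  The top-level node has three
# children (the unrooted star representation), so every internal edge
# corresponds to exactly one tuple position.


def _attach_everywhere(tree, leaf):
    """Yield every tree obtained by attaching ``leaf`` onto one edge."""
    for i, child in enumerate(tree):
        # attach on the edge above child i
        yield tuple((child, leaf) if j == i else tree[j] for j in range(len(tree)))
        if isinstance(child, tuple):
            for sub in _attach_everywhere(child, leaf):
                yield tuple(sub if j == i else tree[j] for j in range(len(tree)))


def _to_newick(tree) -> str:
    def render(node) -> str:
        if isinstance(node, str):
            return node
        return "(" + ",".join(render(c) for c in node) + ")"

    return "(" + ",".join(render(c) for c in tree) + ");"


def enumerate_unrooted_newicks(labels) -> list[str]:
    """All unrooted binary topologies on ``labels`` as Newick strings.

    Counts follow (2L-5)!!: 3 leaves -> 1, 4 -> 3, 5 -> 15, 6 -> 105.
    """
    labels = list(labels)
    if len(labels) < 3:
        raise ValueError("need at least 3 labels")
    trees = [tuple(labels[:3])]
    for leaf in labels[3:]:
        trees = [t for base in trees for t in _attach_everywhere(base, leaf)]
    return [_to_newick(t) for t in trees]


def random_unrooted_newick(labels, rng: np.random.Generator, lengths: bool = False) -> str:
    """One uniform-ish random unrooted binary topology on ``labels``."""
    labels = list(labels)
    tree = tuple(labels[:3])
    for leaf in labels[3:]:
        options = list(_attach_everywhere(tree, leaf))
        tree = options[rng.integers(len(options))]
    nw = _to_newick(tree)
    if lengths:
        import re

        nw = re.sub(
            r"([A-Za-z0-9_]+|\))",
            lambda m: m.group(0) + f":{rng.uniform(0.01, 2.0):.4f}",
            nw[:-1],
        ) + ";"
    return nw


FIVE_LEAVES = ["a", "b", "c", "d", "e"]


@pytest.fixture(scope="session")
def five_leaf_topologies() -> list[str]:
    return enumerate_unrooted_newicks(FIVE_LEAVES)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
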