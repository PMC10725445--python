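"""Shared fixtures and independent oracle helpers.

The oracle helpers here (topology enumeration, split extraction) are written
from the definitions directly and deliberately do not reuse the package's
tree machinery beyond the plain node container, so that tests comparing
against them are genuinely two-route.
"""

from __future__ import annotations

import random

import numpy as np
import pytest

from divtree.data import (CellLineageTree, CellStateTree, ExpressionMatrix,
                          TreeNode)


@pytest.fixture
def small_state_tree() -> CellStateTree:
    """Seven states: root S0 -> (S1, S2); S1 -> (S3, S4); S2 -> (S5, S6)."""
    return CellStateTree.from_newick("((S3,S4)S1,(S5,S6)S2)S0;")


@pytest.fixture
def linear_state_tree() -> CellStateTree:
    """Chain R -> P -> A plus branch P -> B (used in geodesic/MRCA examples)."""
    return CellStateTree.from_newick("((A,B)P)R;")


def enumerate_topologies(leaves):
    """Yield every rooted binary topology over ``leaves`` as nested tuples.

    Count is (2n-3)!! — 3 topologies for 3 leaves, 15 for 4, 105 for 5,
    945 for 6 — generated by inserting each leaf on every branch (including
    above the root) of every smaller tree.
    """
    def insertions(t, leaf):
        yield (t, leaf)
        if isinstance(t, tuple):
            a, b = t
            for s in insertions(a, leaf):
                yield (s, b)
            for s in insertions(b, leaf):
                yield (a, s)

    def build(items):
        if len(items) == 1:
            yield items[0]
            return
        for t in build(items[1:]):
            yield from insertions(t, items[0])

    return build(list(leaves))


def tuple_to_tree(tpl) -> CellLineageTree:
    def make(x):
        if isinstance(x, tuple):
            n = TreeNode(None)
            n.add_child(make(x[0]))
            n.add_child(make(x[1]))
            return n
        return TreeNode(x)

    return CellLineageTree(make(tpl))


def random_topology(leaves, rng: random.Random) -> CellLineageTree:
    """Random rooted binary tree built by naive sequential joins (independent
    of the package's generator)."""
    nodes = [TreeNode(l) for l in leaves]
    while len(nodes) > 1:
        i, j = sorted(rng.sample(range(len(nodes)), 2))
        parent = TreeNode(None)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    return CellLineageTree(nodes[0])


def brute_force_splits(t: CellLineageTree) -> set[frozenset]:
    """Non-trivial splits by direct clade collection, canonicalized to the
    side not containing the alphabetically first leaf."""
    leaves = sorted(t.leaf_names())
    first = leaves[0]
    out = set()

    def clade(n):
        if n.is_leaf:
            return {n.name}
        s = set()
        for c in n.children:
            s |= clade(c)
        return s

    def walk(n):
        for c in n.children:
            side = clade(c)
            if 2 <= len(side) <= len(leaves) - 2:
                canon = frozenset(set(leaves) - side if first in side else side)
                out.add(canon)
            walk(c)

    walk(t.root)
    return out


@pytest.fixture
def rng() -> random.Random:
    return random.Random(1234)


@pytest.fixture
def nprng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_expression(cells, values) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = [f"g{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(list(cells), genes, values)
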