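"""Tree-comparison metrics and barcode-quality statistics.

Tree comparison (identical leaf sets required):

* normalized Robinson-Foulds distance over non-trivial splits;
* Nye similarity — each split pair is scored by Jaccard overlaps of the four
  side pairings, splits are aligned by maximum-weight bipartite matching and
  the matched score sum is normalized to [0, 1];
* clustering information distance — each split is a 2-block clustering of the
  leaves; matched splits contribute their mutual information and the distance
  is the normalized residual entropy.

Barcode quality on a true tree with ancestral barcodes:

* reconstruction potential Q_r — fraction of edges on which the barcode
  changes (an edge without a mutation can never be recovered);
* homoplasy edge ratio Q_h — fraction of edges whose newly introduced
  mutations all recur on other edges (site-aware mutation identity).
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
from scipy.optimize import linear_sum_assignment

from .data import DROPOUT, UNMUTATED, CellLineageTree

Split = tuple[frozenset, frozenset]


def tree_splits(t: CellLineageTree) -> list[Split]:
    """Non-trivial splits (both sides >= 2 leaves), deduplicated in the
    unrooted sense, ordered deterministically."""
    all_leaves = frozenset(t.leaf_names())
    seen: set[frozenset] = set()
    splits: list[Split] = []
    clades: dict[int, frozenset] = {}
    for n in t.postorder():
        if n.is_leaf:
            clades[id(n)] = frozenset([n.name])
        else:
            clades[id(n)] = frozenset().union(*(clades[id(c)] for c in n.children))
        if n.parent is None:
            continue
        side = clades[id(n)]
        other = all_leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        canon = min(side, other, key=lambda s: sorted(s))
        if canon not in seen:
            seen.add(canon)
            splits.append((side, other))
    return splits


def _check_leafsets(t1: CellLineageTree, t2: CellLineageTree) -> None:
    if set(t1.leaf_names()) != set(t2.leaf_names()):
        raise ValueError("trees must share the same leaf set")


def _canon(s: Split) -> frozenset:
    return min(s[0], s[1], key=lambda x: sorted(x))


def rf_distance(t1: CellLineageTree, t2: CellLineageTree) -> float:
    """Normalized RF: |S1 xor S2| / (|S1| + |S2|) over non-trivial splits;
    0 for identical trees, 1 when no split is shared."""
    _check_leafsets(t1, t2)
    s1 = {_canon(s) for s in tree_splits(t1)}
    s2 = {_canon(s) for s in tree_splits(t2)}
    denom = len(s1) + len(s2)
    if denom == 0:
        return 0.0
    return len(s1 ^ s2) / denom


def nye_split_score(s1: Split, s2: Split) -> float:
    """max{min(a_ll, a_rr), min(a_rl, a_lr)} with a_xy the Jaccard ratio of
    the corresponding sides."""
    def jac(a: frozenset, b: frozenset) -> float:
        u = len(a | b)
        return len(a & b) / u if u else 1.0

    a_ll = jac(s1[0], s2[0])
    a_rr = jac(s1[1], s2[1])
    a_lr = jac(s1[0], s2[1])
    a_rl = jac(s1[1], s2[0])
    return max(min(a_ll, a_rr), min(a_rl, a_lr))


def nye_similarity(t1: CellLineageTree, t2: CellLineageTree,
                   return_raw: bool = False):
    """Maximum-weight alignment of non-trivial splits under
    :func:`nye_split_score`, normalized by the larger split count.

    With ``return_raw`` the unnormalized matched sum is also returned.
    """
    _check_leafsets(t1, t2)
    sp1, sp2 = tree_splits(t1), tree_splits(t2)
    if not sp1 and not sp2:
        return (1.0, 0.0) if return_raw else 1.0
    if not sp1 or not sp2:
        return (0.0, 0.0) if return_raw else 0.0
    score = np.array([[nye_split_score(a, b) for b in sp2] for a in sp1])
    ri, ci = linear_sum_assignment(score, maximize=True)
    raw = float(score[ri, ci].sum())
    sim = raw / max(len(sp1), len(sp2))
    return (sim, raw) if return_raw else sim


def _split_entropy(s: Split) -> float:
    n = len(s[0]) + len(s[1])
    h = 0.0
    for part in s:
        p = len(part) / n
        if p > 0:
            h -= p * math.log(p)
    return h


def _split_mutual_info(s1: Split, s2: Split) -> float:
    n = len(s1[0]) + len(s1[1])
    mi = 0.0
    for a in s1:
        for b in s2:
            nij = len(a & b)
            if nij == 0:
                continue
            mi += (nij / n) * math.log(n * nij / (len(a) * len(b)))
    return max(mi, 0.0)


def clustering_info_distance(t1: CellLineageTree, t2: CellLineageTree) -> float:
    """Clustering information distance: splits are matched to maximize total
    mutual clustering information I*; distance = (H1 + H2 - 2 I*)/(H1 + H2),
    with 0/0 defined as 0 (two star trees are identical)."""
    _check_leafsets(t1, t2)
    sp1, sp2 = tree_splits(t1), tree_splits(t2)
    h1 = sum(_split_entropy(s) for s in sp1)
    h2 = sum(_split_entropy(s) for s in sp2)
    if h1 + h2 == 0:
        return 0.0
    if not sp1 or not sp2:
        return 1.0
    mi = np.array([[_split_mutual_info(a, b) for b in sp2] for a in sp1])
    ri, ci = linear_sum_assignment(mi, maximize=True)
    matched = float(mi[ri, ci].sum())
    return (h1 + h2 - 2.0 * matched) / (h1 + h2)


# ---------------------------------------------------------------------------
# Barcode quality on the true tree
# ---------------------------------------------------------------------------

def _tokens(bc: str) -> list[str]:
    return bc.split("\t") if "\t" in bc else list(bc)


def _iter_edges(t: CellLineageTree):
    for n in t.postorder():
        if n.parent is not None:
            if n.parent.barcode is None or n.barcode is None:
                raise ValueError("all nodes must carry barcodes")
            yield n.parent.barcode, n.barcode


def reconstruction_potential(t: CellLineageTree) -> float:
    """Q_r: fraction of edges on which the barcode changes."""
    edges = list(_iter_edges(t))
    if not edges:
        return 0.0
    return sum(u != v for u, v in edges) / len(edges)


def _new_mutations(parent_bc: str, child_bc: str) -> frozenset:
    pu, cv = _tokens(parent_bc), _tokens(child_bc)
    return frozenset((j, cv[j]) for j in range(len(cv))
                     if cv[j] not in (UNMUTATED, DROPOUT) and pu[j] != cv[j])


def homoplasy_edge_ratio(t: CellLineageTree, literal: bool = False) -> float:
    """Q_h: fraction of edges whose newly introduced mutations (site, token)
    all recur on other edges. Edges introducing no mutation are excluded
    from the numerator unless ``literal`` is set (the set-inclusion formula
    taken literally counts them, since the empty set is a subset of
    anything)."""
    edge_sets = [_new_mutations(u, v) for u, v in _iter_edges(t)]
    if not edge_sets:
        return 0.0
    occurrences = Counter(m for s in edge_sets for m in s)
    homoplasy = 0
    for s in edge_sets:
        if not s:
            if literal:
                homoplasy += 1
            continue
        if all(occurrences[m] >= 2 for m in s):
            homoplasy += 1
    return homoplasy / len(edge_sets)


def annotate_barcodes(t: CellLineageTree, barcodes: dict[str, str]) -> CellLineageTree:
    """Attach barcode strings to named tree nodes (in place)."""
    for n in t.postorder():
        if n.name is not None and n.name in barcodes:
            n.barcode = barcodes[n.name]
    return t
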