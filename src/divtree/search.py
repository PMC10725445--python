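"""Per-clone maximum-likelihood subtree search and backbone reattachment.

Cells sharing one barcode are unresolved by the barcode alone; their subtree
(the "gene expression subtree", GES) is found by hill climbing on the tree
log-likelihood with random subtree swap (rSS) proposals and random restarts.
The iteration budget per clone is min(C(n), max_iter) where C(n) is the nth
Catalan number, so tiny clones never waste proposals and large clones are
capped.

The hill climb scores candidate trees with a compact integer-array scorer
(precomputed geodesic/MRCA tables and log transition probabilities); it is
numerically identical to :func:`divtree.likelihood.total_loglik` and tested
against it.
"""

from __future__ import annotations

import math
import random
import zlib
from collections import Counter
from dataclasses import dataclass

import numpy as np

from . import likelihood as lk
from .backbone import UniqueBarcodeIndex, build_backbone
from .data import (BarcodeMatrix, CellLineageTree, CellStateTree,
                   ExpressionMatrix, LikelihoodParams, StateAssignment,
                   TreeNode)
from .states import infer_states_pipeline, select_hvg


@dataclass
class SearchConfig:
    """Local-search knobs: total proposal budget min(C(n), max_iter) per
    clone, up to ``restarts`` additional random initializations, and a local
    optimum is declared after ``patience`` consecutive rejected proposals."""

    max_iter: int = 500
    restarts: int = 3
    patience: int = 100
    seed: int = 0
    nj_init: bool = False    # seed the first restart with expression-NJ

    def __post_init__(self):
        if min(self.max_iter, self.restarts, self.patience) <= 0:
            raise ValueError("search parameters must be positive")


def catalan_budget(n_leaves: int, max_iter: int = 500) -> int:
    """min(C(n), max_iter) with C(n) the nth Catalan number (exact big-int)."""
    if n_leaves < 1:
        raise ValueError("need at least one leaf")
    c = math.comb(2 * n_leaves, n_leaves) // (n_leaves + 1)
    return min(c, max_iter)


# ---------------------------------------------------------------------------
# Compact tree representation used inside the hill climb
# ---------------------------------------------------------------------------

class _ArrayTree:
    """Rooted binary tree over leaves 0..n-1; internal nodes n..2n-2."""

    __slots__ = ("n", "children", "parent", "root")

    def __init__(self, n: int):
        self.n = n
        size = 2 * n - 1 if n > 1 else 1
        self.children: list[list[int] | None] = [None] * size
        self.parent = [-1] * size
        self.root = 0

    def copy(self) -> "_ArrayTree":
        t = _ArrayTree.__new__(_ArrayTree)
        t.n = self.n
        t.children = [c.copy() if c else None for c in self.children]
        t.parent = self.parent.copy()
        t.root = self.root
        return t

    def postorder(self) -> list[int]:
        order, stack = [], [(self.root, False)]
        while stack:
            v, done = stack.pop()
            if done:
                order.append(v)
            else:
                stack.append((v, True))
                if self.children[v]:
                    for c in reversed(self.children[v]):
                        stack.append((c, False))
        return order

    def is_ancestor(self, u: int, v: int) -> bool:
        while v != -1:
            if v == u:
                return True
            v = self.parent[v]
        return False

    def to_lineage_tree(self, leaf_names: list[str]) -> CellLineageTree:
        nodes: dict[int, TreeNode] = {}
        for v in self.postorder():
            node = TreeNode(leaf_names[v] if v < self.n else None)
            if self.children[v]:
                for c in self.children[v]:
                    node.add_child(nodes[c])
            nodes[v] = node
        return CellLineageTree(nodes[self.root])


def _random_array_tree(n: int, rng: random.Random) -> _ArrayTree:
    """Uniform rooted binary topology by sequential random attachment: leaf m
    is inserted on one of the 2m-3 branches (including above the root)."""
    t = _ArrayTree(n)
    if n == 1:
        return t
    t.children[n] = [0, 1]
    t.parent[0] = t.parent[1] = n
    t.root = n
    nodes = [0, 1]          # non-root nodes, each defining the branch above it
    for leaf in range(2, n):
        internal = n + leaf - 1
        pos = rng.randrange(2 * leaf - 1)
        if pos == len(nodes):           # new root above the old one
            t.children[internal] = [t.root, leaf]
            t.parent[t.root] = internal
            nodes.append(t.root)
            t.root = internal
        else:
            x = nodes[pos]
            p = t.parent[x]
            t.children[p][t.children[p].index(x)] = internal
            t.parent[internal] = p
            t.children[internal] = [x, leaf]
            t.parent[x] = internal
            nodes.append(internal)
        t.parent[leaf] = internal
        nodes.append(leaf)
    return t


def _rss_array(t: _ArrayTree, rng: random.Random, max_tries: int = 50) -> _ArrayTree:
    """Random subtree swap on a copy: two non-root, non-nested nodes exchange
    positions. Returns the input unchanged when no valid pair exists (fewer
    than 3 leaves)."""
    if t.n < 3:
        return t
    cand = [v for v in range(len(t.parent)) if v != t.root]
    if len(cand) < 2:
        return t
    for _ in range(max_tries):
        u, v = rng.sample(cand, 2)
        if t.is_ancestor(u, v) or t.is_ancestor(v, u):
            continue
        s = t.copy()
        pu, pv = s.parent[u], s.parent[v]
        s.children[pu][s.children[pu].index(u)] = v
        s.children[pv][s.children[pv].index(v)] = u
        s.parent[u], s.parent[v] = pv, pu
        return s
    return t


def _score_array_tree(t: _ArrayTree, leaf_state: np.ndarray, geo: np.ndarray,
                      mrca: np.ndarray, logpnd: np.ndarray | None,
                      params: LikelihoodParams) -> float:
    """Three-term log-likelihood on the compact representation; the
    transition table is built from this subtree's own edges."""
    n = t.n
    if n == 1:
        return 0.0
    size = 2 * n - 1
    state = [0] * size
    log_a = math.log(params.p_asym)
    log_s = math.log(1.0 - params.p_asym)
    lad = 0.0
    lnd = 0.0
    lengths: list[float] = []
    n_inf = 0
    for v in t.postorder():
        ch = t.children[v]
        if ch is None:
            state[v] = leaf_state[v]
            continue
        a, b = ch
        sa, sb = state[a], state[b]
        state[v] = sa if sa == sb else mrca[sa, sb]
        lad += log_s if sa == sb else log_a
        if logpnd is not None and a < n and b < n:
            lnd += logpnd[a, b]
        for c in ch:
            d = geo[state[v], state[c]]
            if d == np.inf:
                n_inf += 1
            else:
                lengths.append(float(d))
    if lengths:
        cnt = Counter(lengths)
        total = len(lengths)
        le = sum(c * math.log(c / total) for c in cnt.values())
    else:
        le = 0.0
    le += params.inf_geodesic_penalty * n_inf
    return le + params.lambda1 * lad + params.lambda2 * lnd


def _state_tables(st: CellStateTree) -> tuple[dict[str, int], np.ndarray, np.ndarray]:
    states = st.states
    idx = {s: i for i, s in enumerate(states)}
    k = len(states)
    geo = np.full((k, k), np.inf)
    mrca = np.zeros((k, k), dtype=int)
    for s1 in states:
        for s2 in states:
            geo[idx[s1], idx[s2]] = st.geodesic(s1, s2)
            mrca[idx[s1], idx[s2]] = idx[st.mrca(s1, s2)]
    return idx, geo, mrca


def random_binary_tree(leaf_ids: list[str], rng: random.Random | int = 0) -> CellLineageTree:
    """Uniformly random rooted binary topology over the given leaves."""
    if isinstance(rng, int):
        rng = random.Random(rng)
    return _random_array_tree(len(leaf_ids), rng).to_lineage_tree(list(leaf_ids))


def rss_move(t: CellLineageTree, rng: random.Random | int = 0) -> CellLineageTree:
    """Random subtree swap on a :class:`CellLineageTree` (binary, same leaf set)."""
    if isinstance(rng, int):
        rng = random.Random(rng)
    leaves = t.leaf_names()
    at, names = _from_lineage_tree(t)
    moved = _rss_array(at, rng)
    return moved.to_lineage_tree(names)


def _from_lineage_tree(t: CellLineageTree) -> tuple[_ArrayTree, list[str]]:
    leaves = t.leaves()
    names = [l.name for l in leaves]
    n = len(leaves)
    at = _ArrayTree(n)
    counter = [n]
    index: dict[int, int] = {}
    for node in t.postorder():
        if node.is_leaf:
            index[id(node)] = names.index(node.name)
        else:
            v = counter[0]
            counter[0] += 1
            index[id(node)] = v
            at.children[v] = [index[id(c)] for c in node.children]
            for c in node.children:
                at.parent[index[id(c)]] = v
    at.root = index[id(t.root)]
    return at, names


def optimize_ges(cells: list[str], em: ExpressionMatrix | None,
                 leaf_states: StateAssignment, st: CellStateTree,
                 params: LikelihoodParams | None = None,
                 cfg: SearchConfig | None = None,
                 kernel_values: np.ndarray | None = None,
                 ) -> tuple[CellLineageTree, float]:
    """Find the maximum-likelihood binary subtree over one clone's cells.

    Sizes 1-3 are solved directly (3 cells: all 3 rooted topologies); larger
    clones use rSS hill climbing with random restarts under the Catalan
    iteration budget. ``kernel_values`` may supply precomputed expression
    rows (aligned with ``cells``) for the diffusion kernel, otherwise they
    are taken from ``em``.
    """
    params = params or LikelihoodParams()
    cfg = cfg or SearchConfig()
    n = len(cells)
    idx, geo, mrca = _state_tables(st)
    leaf_state = np.array([idx[leaf_states[c]] for c in cells], dtype=int)

    logpnd = None
    if params.lambda2 != 0.0 and n >= 2:
        if kernel_values is None:
            if em is None:
                raise ValueError("expression data required when lambda2 != 0")
            kernel_values = np.log1p(em.subset_cells(cells).values)
        P, _ = lk.diffusion_transition(kernel_values, params.sigma)
        logpnd = lk.log_sym_pnd(P)

    def score(at: _ArrayTree) -> float:
        return _score_array_tree(at, leaf_state, geo, mrca, logpnd, params)

    if n == 1:
        return CellLineageTree(TreeNode(cells[0])), 0.0
    if n == 2:
        at = _ArrayTree(2)
        at.children[2] = [0, 1]
        at.parent[0] = at.parent[1] = 2
        at.root = 2
        return at.to_lineage_tree(cells), score(at)
    rng = random.Random(cfg.seed)
    if n == 3:
        best, best_s = None, -np.inf
        for out in range(3):
            at = _ArrayTree(3)
            a, b = [x for x in range(3) if x != out]
            at.children[3] = [a, b]
            at.children[4] = [3, out]
            at.parent[a] = at.parent[b] = 3
            at.parent[3] = at.parent[out] = 4
            at.root = 4
            s = score(at)
            if s > best_s:
                best, best_s = at, s
        return best.to_lineage_tree(cells), best_s

    budget = catalan_budget(n, cfg.max_iter)   # per local search (restart)
    best, best_s = None, -np.inf
    for start in range(1 + cfg.restarts):
        if start == 0 and cfg.nj_init and kernel_values is not None:
            from scipy.spatial.distance import pdist, squareform
            from .backbone import neighbor_joining
            D = squareform(pdist(np.asarray(kernel_values, dtype=float)))
            nj = neighbor_joining(D, cells)
            cur, _names = _from_lineage_tree(nj)
            order = [_names.index(c) for c in cells]
            remap = {order[i]: i for i in range(n)}  # leaf slots by cell order
            cur.children = [None if ch is None else
                            [remap.get(x, x) for x in ch]
                            for ch in cur.children]
            for v, ch in enumerate(cur.children):
                if ch:
                    for x in ch:
                        cur.parent[x] = v
        else:
            cur = _random_array_tree(n, rng)
        cur_s = score(cur)
        iters = 0
        rejects = 0
        while iters < budget and rejects < cfg.patience:
            cand = _rss_array(cur, rng)
            iters += 1
            s = score(cand)
            if s > cur_s:           # strict improvement; ties keep incumbent
                cur, cur_s = cand, s
                rejects = 0
            else:
                rejects += 1
        if cur_s > best_s:
            best, best_s = cur, cur_s
    return best.to_lineage_tree(cells), best_s


def attach_subtrees(backbone: CellLineageTree, index: UniqueBarcodeIndex,
                    ges_map: dict[str, CellLineageTree]) -> CellLineageTree:
    """Step D: replace each backbone leaf (a unique barcode) by its clone's
    optimized subtree; the result's leaves are the N cells."""
    tree = backbone.copy()
    seen: set[str] = set()
    for leaf in tree.leaves():
        bc = leaf.name
        if bc not in ges_map:
            raise KeyError(f"no subtree for barcode {bc!r}")
        ges = ges_map[bc].copy()
        for cname in ges.leaf_names():
            if cname in seen:
                raise ValueError(f"cell {cname!r} appears in multiple clones")
            seen.add(cname)
        sub = ges.root
        sub.length = leaf.length
        if leaf.parent is None:
            tree = CellLineageTree(sub)
        else:
            par = leaf.parent
            par.children[par.children.index(leaf)] = sub
            sub.parent = par
    return tree


def _clone_seed(global_seed: int, barcode: str) -> int:
    return (global_seed * 1_000_003 + zlib.crc32(barcode.encode())) % (2 ** 31)


def reconstruct(bm: BarcodeMatrix, em: ExpressionMatrix | None,
                state_tree: CellStateTree | None = None,
                leaf_states: StateAssignment | None = None,
                params: LikelihoodParams | None = None,
                cfg: SearchConfig | None = None,
                n_hvg: int = 100, k_states: int = 7, n_pcs: int = 20,
                root_state: str | None = None, root_cell: str | None = None,
                backbone_tree: CellLineageTree | None = None,
                ) -> CellLineageTree:
    """End-to-end reconstruction: backbone (A), states (B), per-clone subtree
    search (C), reattachment (D). Deterministic given ``cfg.seed``; clones
    are processed in lexicographic order with derived per-clone seeds."""
    params = params or LikelihoodParams()
    cfg = cfg or SearchConfig()
    if backbone_tree is not None:
        from .backbone import collapse_unique_barcodes
        index = collapse_unique_barcodes(bm)
        backbone = backbone_tree
        if sorted(backbone.leaf_names()) != index.barcodes:
            raise ValueError("backbone leaves do not match the unique barcodes")
    else:
        backbone, index = build_backbone(bm)

    if state_tree is None or leaf_states is None:
        if em is None:
            raise ValueError("expression required to infer states")
        inf_states, inf_tree = infer_states_pipeline(
            em, k=k_states, n_hvg=n_hvg, n_pcs=n_pcs, seed=cfg.seed,
            root_state=root_state, root_cell=root_cell)
        leaf_states = leaf_states or inf_states
        state_tree = state_tree or inf_tree

    kernel = None
    if em is not None and params.lambda2 != 0.0:
        hvg = select_hvg(em, n_hvg)
        kernel = np.log1p(hvg.values)
        cell_row = {c: i for i, c in enumerate(hvg.cell_ids)}

    ges_map: dict[str, CellLineageTree] = {}
    for bc in index.barcodes:
        cells = index.members[bc]
        kv = kernel[[cell_row[c] for c in cells]] if kernel is not None else None
        clone_cfg = SearchConfig(cfg.max_iter, cfg.restarts, cfg.patience,
                                 _clone_seed(cfg.seed, bc))
        tree, _ = optimize_ges(cells, em, leaf_states, state_tree,
                               params, clone_cfg, kernel_values=kv)
        ges_map[bc] = tree
    return attach_subtrees(backbone, index, ges_map)
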