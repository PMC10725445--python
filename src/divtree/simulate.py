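"""Synthetic ground truth: division trees with paired barcodes and expression.

The generator emulates a CRISPR lineage-recorder experiment:

* a full binary division tree of ``n_generations`` doublings, with cell
  states following an asymmetric-division model on a rooted state tree (with
  probability ``p_asym`` one daughter advances to a child state, the other
  keeps the parent state);
* per-site irreversible barcode edits — an unedited site mutates with
  probability ``mu`` per division to a token drawn from a biased (geometric)
  outcome distribution, and when two or more edits land in the same division
  the target sites strictly between the outermost new edits are excised
  ("-"), heritably;
* state-dependent expression: each state has a mean profile placed along the
  state tree so that nearby states are transcriptomically similar, plus
  i.i.d. Gaussian noise (optionally Poisson-sampled counts).

All randomness flows from ``SimConfig.seed`` through per-stage streams, so a
config reproduces bit-identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .backbone import collapse_unique_barcodes
from .data import (DROPOUT, UNMUTATED, BarcodeMatrix, CellLineageTree,
                   CellStateTree, ExpressionMatrix, StateAssignment, TreeNode)

# 20 single-character mutation tokens
_TOKENS = [str(i) for i in range(1, 10)] + list("abcdefghijk")


def default_state_tree(n_states: int = 52) -> CellStateTree:
    """Balanced binary state tree with ``n_states`` states (heap-shaped).

    Real differentiation hierarchies discretized at a fine step yield dozens
    of states, so transitions keep occurring throughout the simulated
    generations; the default of 52 states (depth 5) reflects that regime.
    """
    nodes = {i: TreeNode(f"S{i - 1}") for i in range(1, n_states + 1)}
    for i in range(2, n_states + 1):
        nodes[i // 2].add_child(nodes[i])
    return CellStateTree(nodes[1])


def geometric_outcome_weights(n_tokens: int = 20, q: float = 0.3) -> np.ndarray:
    """Biased edit-outcome law: w_r proportional to (1-q)^r."""
    w = (1.0 - q) ** np.arange(n_tokens)
    return w / w.sum()


def geometric_site_weights(n_sites: int, q: float = 0.3) -> np.ndarray:
    """Biased per-site cut propensities, same geometric law as the outcomes.

    In real recorders edits are far from uniform across target sites; a few
    hot sites absorb most cuts and are scattered along the array rather than
    clustered. Weight ranks are therefore spread over positions with a
    golden-ratio (low-discrepancy) permutation, so that simultaneous cuts at
    hot sites can excise substantial stretches of the array. Per-site edit
    probabilities are these weights rescaled so their mean equals the
    nominal rate ``mu`` (capped at 1)."""
    geom = (1.0 - q) ** np.arange(n_sites)
    geom /= geom.sum()
    phi = (np.sqrt(5.0) - 1.0) / 2.0
    u = ((np.arange(n_sites) + 1) * phi) % 1.0
    w = np.empty(n_sites)
    w[np.argsort(u)] = geom
    return w


@dataclass
class SimConfig:
    n_generations: int = 10          # leaves = 2^d
    n_sites: int = 16
    mu: float = 0.1                  # per-site per-division edit probability
    p_asym: float = 0.8
    outcome_weights: np.ndarray | None = None   # default: geometric, 20 tokens
    site_weights: np.ndarray | None = None      # default: geometric over sites
    dropout: bool = True             # excision dropout between same-division edits
    capture_dropout_rate: float = 0.0
    state_tree: CellStateTree | None = None
    n_genes: int = 200
    mean_separation: float = 5.0
    noise_scale: float = 1.0
    count_model: bool = False
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.mu <= 1.0):
            raise ValueError("mu must lie in [0, 1]")
        if self.outcome_weights is None:
            self.outcome_weights = geometric_outcome_weights()
        w = np.asarray(self.outcome_weights, dtype=float)
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("outcome_weights must be a probability vector")
        self.outcome_weights = w
        if self.site_weights is None:
            self.site_weights = geometric_site_weights(self.n_sites)
        sw = np.asarray(self.site_weights, dtype=float)
        if len(sw) != self.n_sites or np.any(sw < 0) or not np.isclose(sw.sum(), 1.0):
            raise ValueError("site_weights must be a probability vector over sites")
        self.site_weights = sw
        if self.state_tree is None:
            self.state_tree = default_state_tree()


@dataclass
class GroundTruth:
    tree: CellLineageTree            # states + barcodes on every node
    barcodes: BarcodeMatrix          # leaves only
    expression: ExpressionMatrix
    leaf_states: StateAssignment
    state_tree: CellStateTree
    all_barcodes: dict               # node name -> barcode string

    def leaf_ids(self) -> list[str]:
        return self.barcodes.cell_ids


def _rng(cfg: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stage])


def simulate_division_tree(cfg: SimConfig,
                           rng: np.random.Generator | None = None) -> CellLineageTree:
    """Full binary tree of depth ``n_generations`` with asymmetric-division
    state labels; nodes are named heap-style ("a<i>" internal, "c<i>" leaf)."""
    rng = rng if rng is not None else _rng(cfg, 0)
    st = cfg.state_tree
    children_of = {s: [c.name for c in st._nodes[s].children] for s in st.states}
    d = cfg.n_generations
    root = TreeNode(f"a1" if d > 0 else "c1")
    root.state = st.root.name
    frontier = [(root, 1, 0)]
    while frontier:
        node, idx, depth = frontier.pop()
        if depth == d:
            continue
        kids = children_of[node.state]
        s1 = s2 = node.state
        if kids and rng.random() < cfg.p_asym:
            adv = kids[rng.integers(len(kids))]
            if rng.random() < 0.5:
                s1 = adv
            else:
                s2 = adv
        for i, s in ((2 * idx, s1), (2 * idx + 1, s2)):
            child_depth = depth + 1
            name = f"c{i}" if child_depth == d else f"a{i}"
            ch = node.add_child(TreeNode(name))
            ch.state = s
            frontier.append((ch, i, child_depth))
    return CellLineageTree(root)


def simulate_barcodes(tree: CellLineageTree, cfg: SimConfig,
                      rng: np.random.Generator | None = None) -> dict:
    """Edit barcodes down the tree (in place on ``node.barcode``); returns a
    node-name -> barcode-string map covering every node."""
    rng = rng if rng is not None else _rng(cfg, 1)
    m = cfg.n_sites
    tokens = np.array(_TOKENS[: len(cfg.outcome_weights)])
    # per-site edit probability: biased propensities rescaled to mean mu
    site_mu = np.minimum(cfg.site_weights * cfg.mu * m, 1.0)
    out: dict = {}
    order = list(tree.preorder())
    for node in order:
        if node.parent is None:
            bc = [UNMUTATED] * m
        else:
            bc = list(node.parent.barcode)
            # fixed-length draws per division keep the mutation stream
            # identical whether or not dropout is enabled
            u = rng.random(m)
            toks = rng.choice(len(tokens), size=m, p=cfg.outcome_weights)
            hits = [j for j in range(m)
                    if bc[j] == UNMUTATED and u[j] < site_mu[j]]
            for j in hits:
                bc[j] = str(tokens[toks[j]])
            if cfg.dropout and len(hits) >= 2:
                for j in range(min(hits) + 1, max(hits)):
                    bc[j] = DROPOUT
        node.barcode = "".join(bc)
        out[node.name] = node.barcode
    if cfg.capture_dropout_rate > 0:
        leaves = tree.leaves()
        mask = rng.random(len(leaves)) < cfg.capture_dropout_rate
        for leaf, hit in zip(leaves, mask):
            if hit:
                leaf.barcode = DROPOUT * m
                out[leaf.name] = leaf.barcode
    return out


def simulate_expression(tree: CellLineageTree, leaf_states: StateAssignment,
                        cfg: SimConfig,
                        rng: np.random.Generator | None = None) -> ExpressionMatrix:
    """State-dependent expression via branch marker genes.

    Each state-tree edge gets one marker gene expressed (at
    ``mean_separation``) in every state at or below that edge; the remaining
    genes are flat "housekeeping" background. State means then embed the
    state tree as an exact tree metric (squared distance = path length x
    separation^2), so states form a manifold along the tree. Cells add
    i.i.d. Gaussian noise, clipped at zero (Poisson counts when
    ``count_model``); marker assignment to gene indices is randomized.
    """
    rng = rng if rng is not None else _rng(cfg, 2)
    st = cfg.state_tree
    states = st.states
    non_root = [s for s in states if s != st.root.name]
    if cfg.n_genes < len(non_root):
        raise ValueError("n_genes must be at least the number of state-tree edges")
    marker_gene = dict(zip(non_root,
                           rng.permutation(cfg.n_genes)[: len(non_root)]))
    baseline = 1.0
    means: dict[str, np.ndarray] = {}
    for s in states:
        mu = np.full(cfg.n_genes, baseline)
        for anc in st.ancestor_path(s)[1:]:
            mu[marker_gene[anc]] += cfg.mean_separation
        means[s] = mu
    cells = list(leaf_states)
    vals = np.stack([means[leaf_states[c]] for c in cells])
    if cfg.noise_scale > 0:
        vals = vals + rng.normal(scale=cfg.noise_scale, size=vals.shape)
    vals = np.clip(vals, 0.0, None)
    if cfg.count_model:
        vals = rng.poisson(vals).astype(float)
    genes = [f"g{j}" for j in range(cfg.n_genes)]
    return ExpressionMatrix(cells, genes, vals)


def simulate(cfg: SimConfig) -> GroundTruth:
    """Compose tree, barcodes and expression into a reproducible ground truth."""
    tree = simulate_division_tree(cfg)
    all_bc = simulate_barcodes(tree, cfg)
    leaves = tree.leaves()
    leaf_states = {l.name: l.state for l in leaves}
    bm = BarcodeMatrix.from_strings([l.name for l in leaves],
                                    [l.barcode for l in leaves])
    em = simulate_expression(tree, leaf_states, cfg)
    return GroundTruth(tree, bm, em, leaf_states, cfg.state_tree, all_bc)


def sharing_fraction(bm: BarcodeMatrix) -> float:
    """Fraction of cells whose barcode is shared with at least two other
    cells (clone size >= 3)."""
    index = collapse_unique_barcodes(bm)
    shared = sum(len(v) for v in index.members.values() if len(v) >= 3)
    return shared / bm.n_cells
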