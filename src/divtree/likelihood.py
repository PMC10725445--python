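"""Tree likelihood: ancestral cell states plus a three-term log-likelihood.

A candidate division tree T is scored as

    L(T) = L_E(T) + lambda1 * L_ad(T) + lambda2 * L_nd(T)

* ``L_E`` (state transition): ancestral states are inferred bottom-up (equal
  children keep their state, unequal children get the MRCA on the state
  tree); each edge's parent->child transition is scored by the empirical
  probability of its graph-geodesic length among all finite-geodesic edges;
  edges with no directed path on the state tree incur a flat penalty
  (default -50) on the log-likelihood.
* ``L_ad`` (asymmetric division): each division contributes log(p_a) when the
  daughters differ in state and log(1 - p_a) when they agree. With the
  default p_a = 0.8, asymmetric divisions are favored.
* ``L_nd`` (neighbor distance): sibling leaf pairs (cherries) contribute the
  log diffusion-map transition probability between their expression
  profiles, symmetrized by averaging the two directions.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .data import (CellLineageTree, CellStateTree, ExpressionMatrix,
                   LikelihoodParams, StateAssignment, TreeNode)

_LOG_FLOOR = 1e-300


@dataclass
class TransitionTable:
    """Empirical distribution of geodesic lengths over finite-geodesic edges."""

    probs: dict[float, float]     # geodesic length -> probability
    n_finite: int
    n_infinite: int

    def prob(self, d: float) -> float:
        return self.probs.get(d, 0.0)


def infer_ancestral_states(t: CellLineageTree, leaf_states: StateAssignment,
                           st: CellStateTree) -> StateAssignment:
    """Post-order ancestral state assignment; annotates ``node.state`` in
    place and returns a node -> state mapping (leaves keyed by name)."""
    out: dict = {}
    for n in t.postorder():
        if n.is_leaf:
            if n.name not in leaf_states:
                raise KeyError(f"no state for leaf {n.name!r}")
            s = leaf_states[n.name]
            if s not in st._nodes:
                raise KeyError(f"leaf state {s!r} missing from state tree")
        else:
            child_states = [c.state for c in n.children]
            s = child_states[0]
            for cs in child_states[1:]:
                s = cs if s == cs else st.mrca(s, cs)
        n.state = s
        out[n.name if n.name is not None else n] = s
    return out


def geodesic(st: CellStateTree, s1: str, s2: str) -> float:
    """Directed path length s1 -> s2 on the state tree; +inf if unreachable."""
    return st.geodesic(s1, s2)


def _edge_geodesics(t: CellLineageTree, st: CellStateTree) -> tuple[list[float], int]:
    finite: list[float] = []
    n_inf = 0
    for n in t.postorder():
        if n.parent is None:
            continue
        d = st.geodesic(n.parent.state, n.state)
        if math.isinf(d):
            n_inf += 1
        else:
            finite.append(d)
    return finite, n_inf


def transition_table(t: CellLineageTree, st: CellStateTree) -> TransitionTable:
    """Empirical P(geodesic length) over the tree's finite-geodesic edges."""
    finite, n_inf = _edge_geodesics(t, st)
    if not finite:
        return TransitionTable({}, 0, n_inf)
    cnt = Counter(finite)
    total = len(finite)
    return TransitionTable({d: c / total for d, c in cnt.items()}, total, n_inf)


def state_transition_loglik(t: CellLineageTree, st: CellStateTree,
                            penalty: float = -50.0) -> float:
    """L_E: sum of log empirical transition probabilities, plus ``penalty``
    per infinite-geodesic edge. Requires states on all nodes."""
    finite, n_inf = _edge_geodesics(t, st)
    if not finite:
        return penalty * n_inf
    cnt = Counter(finite)
    total = len(finite)
    ll = sum(c * math.log(c / total) for c in cnt.values())
    return ll + penalty * n_inf


def asym_division_loglik(t: CellLineageTree, p_a: float = 0.8) -> float:
    """L_ad: log(1-p_a) per symmetric division, log(p_a) per asymmetric one."""
    ll = 0.0
    log_a, log_s = math.log(p_a), math.log(1.0 - p_a)
    for n in t.postorder():
        if n.is_leaf:
            continue
        if len(n.children) != 2:
            raise ValueError("asymmetric-division likelihood needs a binary tree")
        a, b = n.children
        ll += log_s if a.state == b.state else log_a
    return ll


def auto_sigma(values: np.ndarray) -> float:
    """Median pairwise Euclidean distance; falls back to 1 when degenerate."""
    if values.shape[0] < 2:
        return 1.0
    med = float(np.median(pdist(values)))
    return med if med > 0 else 1.0


def diffusion_transition(em, sigma: float | str = "auto"):
    """Diffusion-map transition probabilities P_nd between cells.

    Returns ``(P, cell_ids)`` where ``P[i, j]`` is the density-normalized
    transition probability from cell i to cell j (diagonal zero; each row
    sums to 1 over j != i).
    """
    if isinstance(em, ExpressionMatrix):
        values, cells = em.values, em.cell_ids
    else:
        values = np.asarray(em, dtype=float)
        cells = list(range(values.shape[0]))
    n = values.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells")
    if sigma == "auto":
        sigma = auto_sigma(values)
    d2 = squareform(pdist(values)) ** 2
    K = np.exp(-d2 / (2.0 * float(sigma) ** 2))
    Z = K.sum(axis=1)                       # includes K_ii = 1
    A = K / (Z[:, None] * Z[None, :])
    np.fill_diagonal(A, 0.0)
    Zhat = A.sum(axis=1)
    P = A / Zhat[:, None]
    return P, cells


def log_sym_pnd(P: np.ndarray) -> np.ndarray:
    """Log of the symmetrized transition matrix, floored to avoid -inf."""
    return np.log(np.maximum((P + P.T) / 2.0, _LOG_FLOOR))


def cherries(t: CellLineageTree) -> list[tuple[str, str]]:
    """Unordered sibling leaf pairs."""
    out = []
    for n in t.postorder():
        if len(n.children) == 2 and all(c.is_leaf for c in n.children):
            out.append((n.children[0].name, n.children[1].name))
    return out


def neighbor_distance_loglik(t: CellLineageTree, P: np.ndarray,
                             cell_index: dict, symmetrize: bool = True) -> float:
    """L_nd: sum over cherries of log((P_ij + P_ji) / 2).

    P_nd is asymmetric but sibling pairs are unordered; the default averages
    the two directions. ``symmetrize=False`` instead evaluates the ordered
    direction low-index -> high-index.
    """
    logp = (log_sym_pnd(P) if symmetrize
            else np.log(np.maximum(P, _LOG_FLOOR)))
    ll = 0.0
    for a, b in cherries(t):
        if a not in cell_index or b not in cell_index:
            raise KeyError(f"cherry cell {a!r}/{b!r} absent from expression set")
        i, j = cell_index[a], cell_index[b]
        if not symmetrize and i > j:
            i, j = j, i
        ll += logp[i, j]
    return ll


def total_loglik(t: CellLineageTree, leaf_states: StateAssignment,
                 st: CellStateTree, em: ExpressionMatrix | None,
                 params: LikelihoodParams | None = None,
                 pnd: tuple[np.ndarray, dict] | None = None) -> float:
    """L(T) = L_E + lambda1 * L_ad + lambda2 * L_nd (ancestral states are
    inferred first). ``pnd`` may carry a precomputed ``(P, cell_index)``."""
    params = params or LikelihoodParams()
    infer_ancestral_states(t, leaf_states, st)
    ll = state_transition_loglik(t, st, params.inf_geodesic_penalty)
    ll += params.lambda1 * asym_division_loglik(t, params.p_asym)
    if params.lambda2 != 0.0:
        if pnd is None:
            if em is None:
                raise ValueError("expression data required when lambda2 != 0")
            leaf_names = t.leaf_names()
            sub = em.subset_cells(leaf_names)
            # kernel operates in log1p space, matching the HVG preprocessing
            P, _ = diffusion_transition(np.log1p(sub.values), params.sigma)
            pnd = (P, {c: i for i, c in enumerate(leaf_names)})
        P, cell_index = pnd
        ll += params.lambda2 * neighbor_distance_loglik(t, P, cell_index)
    return ll


def loglik_terms(t: CellLineageTree, leaf_states: StateAssignment,
                 st: CellStateTree, em: ExpressionMatrix | None,
                 params: LikelihoodParams | None = None,
                 pnd: tuple[np.ndarray, dict] | None = None) -> dict:
    """Per-term breakdown plus the weighted total (for reporting)."""
    params = params or LikelihoodParams()
    infer_ancestral_states(t, leaf_states, st)
    le = state_transition_loglik(t, st, params.inf_geodesic_penalty)
    lad = asym_division_loglik(t, params.p_asym)
    if pnd is None and em is not None:
        leaf_names = t.leaf_names()
        sub = em.subset_cells(leaf_names)
        P, _ = diffusion_transition(np.log1p(sub.values), params.sigma)
        pnd = (P, {c: i for i, c in enumerate(leaf_names)})
    lnd = (neighbor_distance_loglik(t, pnd[0], pnd[1]) if pnd is not None else 0.0)
    return {"state_transition": le, "asym_division": lad,
            "neighbor_distance": lnd,
            "total": le + params.lambda1 * lad + params.lambda2 * lnd}


def estimate_p_asym(t: CellLineageTree, leaf_states: StateAssignment) -> float:
    """Naive plug-in estimate of the asymmetric-division rate: the fraction
    of cherries whose two leaf states differ. Experimental; the fixed default
    of 0.8 is used everywhere unless explicitly overridden."""
    pairs = cherries(t)
    if not pairs:
        return 0.5
    diff = sum(leaf_states[a] != leaf_states[b] for a, b in pairs)
    return diff / len(pairs)
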