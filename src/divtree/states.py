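"""Cell-state inference from expression: HVG selection, PCA, k-means, and a
rooted state tree from an MST over cluster centroids.

The state tree stands in for a full trajectory-inference run: only the rooted
tree of cluster labels is needed downstream, and a minimum spanning tree over
cluster centroids in PCA space is exactly the lineage-structure step of
MST-based trajectory methods. Supplying a known state tree as Newick bypasses
this module entirely.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import squareform, pdist
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .data import CellStateTree, ExpressionMatrix, StateAssignment, TreeNode


def select_hvg(em: ExpressionMatrix, n_genes: int = 100) -> ExpressionMatrix:
    """Keep the ``n_genes`` genes with the highest variance of log1p values."""
    if em.n_genes < n_genes:
        warnings.warn(f"only {em.n_genes} genes available, keeping all")
        return em
    var = np.log1p(em.values).var(axis=0)
    order = np.argsort(-var, kind="stable")[:n_genes]
    keep = sorted(order)  # preserve input gene order
    return ExpressionMatrix(em.cell_ids, [em.gene_ids[i] for i in keep],
                            em.values[:, keep])


def reduce_pca(em: ExpressionMatrix, n_pcs: int = 20) -> np.ndarray:
    """Centered-log1p PCA embedding (cells x n_pcs), full SVD for determinism."""
    if n_pcs > min(em.n_cells, em.n_genes):
        raise ValueError("n_pcs exceeds matrix rank bound")
    x = np.log1p(em.values)
    x = x - x.mean(axis=0)
    return PCA(n_components=n_pcs, svd_solver="full").fit_transform(x)


def cluster_states(embedding: np.ndarray, cell_ids: list[str], k: int = 7,
                   seed: int = 0) -> StateAssignment:
    """Seeded k-means; labels are the strings "0".."k-1"."""
    if k > len(cell_ids):
        raise ValueError("more clusters than cells")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(np.asarray(embedding, dtype=float))
    return {c: str(l) for c, l in zip(cell_ids, labels)}


def infer_state_tree(embedding: np.ndarray, sa: StateAssignment,
                     root_state: str | None = None,
                     root_cell: str | None = None) -> CellStateTree:
    """Rooted state tree: MST of cluster-centroid Euclidean distances,
    directed away from the root state.

    The root can be named directly (``root_state``) or through a cell
    (``root_cell``, whose assigned state becomes the root).
    """
    cells = list(sa)
    emb = np.asarray(embedding, dtype=float)
    if emb.shape[0] != len(cells):
        raise ValueError("embedding rows must match state assignment")
    if root_cell is not None:
        root_state = sa[root_cell]
    if root_state is None:
        raise ValueError("root_state or root_cell is required")
    states = sorted(set(sa.values()))
    if root_state not in states:
        raise ValueError(f"root state {root_state!r} not among assigned states")
    if len(states) == 1:
        return CellStateTree(TreeNode(states[0]))
    centroids = np.stack([
        emb[[i for i, c in enumerate(cells) if sa[c] == s]].mean(axis=0)
        for s in states
    ])
    dist = squareform(pdist(centroids))
    mst = minimum_spanning_tree(dist).toarray()
    adj: dict[int, list[int]] = {i: [] for i in range(len(states))}
    for i, j in zip(*np.nonzero(mst)):
        adj[int(i)].append(int(j))
        adj[int(j)].append(int(i))
    nodes = {s: TreeNode(s) for s in states}
    seen = {root_state}
    stack = [states.index(root_state)]
    while stack:
        i = stack.pop()
        for j in sorted(adj[i]):
            s = states[j]
            if s not in seen:
                seen.add(s)
                nodes[states[i]].add_child(nodes[s])
                stack.append(j)
    return CellStateTree(nodes[root_state])


def infer_states_pipeline(em: ExpressionMatrix, k: int = 7, n_hvg: int = 100,
                          n_pcs: int = 20, seed: int = 0,
                          root_state: str | None = None,
                          root_cell: str | None = None,
                          ) -> tuple[StateAssignment, CellStateTree]:
    """HVG -> PCA -> k-means -> rooted centroid-MST state tree."""
    hvg = select_hvg(em, n_hvg)
    emb = reduce_pca(hvg, min(n_pcs, min(hvg.n_cells, hvg.n_genes)))
    sa = cluster_states(emb, em.cell_ids, k=k, seed=seed)
    st = infer_state_tree(emb, sa, root_state=root_state, root_cell=root_cell)
    return sa, st
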