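"""Backbone construction: collapse identical barcodes, Neighbor Joining.

Cells sharing an identical barcode are collapsed into one "unique barcode"
leaf; a Hamming-distance Neighbor-Joining tree over the unique barcodes gives
the backbone that the per-clone expression subtrees are later attached to.

Dropout ("-") is treated as a first-class symbol that matches only itself:
excision dropouts are heritable, so shared dropout carries lineage signal.

The backbone is rooted by appending an artificial fully-unedited outgroup
(all sites "0"), running NJ, rooting on the outgroup edge and deleting the
outgroup — mirroring the fact that the recorder starts unedited at the root
of the lineage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import BarcodeMatrix, CellLineageTree, TreeNode, UNMUTATED

_OUTGROUP = "__outgroup__"


@dataclass
class UniqueBarcodeIndex:
    """Distinct barcodes and the cells carrying each one."""

    barcodes: list[str]                 # lexicographically sorted
    members: dict[str, list[str]]       # barcode -> cell ids (input order)
    site_count: int

    @property
    def k(self) -> int:
        return len(self.barcodes)

    def clone_sizes(self) -> dict[str, int]:
        return {b: len(self.members[b]) for b in self.barcodes}


def collapse_unique_barcodes(bm: BarcodeMatrix) -> UniqueBarcodeIndex:
    """Group cells by identical barcode; order is lexicographic by barcode."""
    members: dict[str, list[str]] = {}
    for cid, bc in zip(bm.cell_ids, bm.barcode_strings()):
        members.setdefault(bc, []).append(cid)
    return UniqueBarcodeIndex(sorted(members), members, bm.site_count)


def barcode_hamming(b1, b2) -> int:
    """Positionwise mismatch count; "-" matches only "-"."""
    s1 = b1.split("\t") if isinstance(b1, str) and "\t" in b1 else list(b1)
    s2 = b2.split("\t") if isinstance(b2, str) and "\t" in b2 else list(b2)
    if len(s1) != len(s2):
        raise ValueError(f"length mismatch: {len(s1)} vs {len(s2)}")
    return sum(a != b for a, b in zip(s1, s2))


def hamming_matrix(barcodes: list[str]) -> np.ndarray:
    toks = np.array([b.split("\t") if "\t" in b else list(b) for b in barcodes],
                    dtype=object)
    diff = toks[:, None, :] != toks[None, :, :]
    return diff.sum(axis=2).astype(float)


def neighbor_joining(D, labels: list[str]) -> CellLineageTree:
    """Classic Neighbor Joining (Saitou & Nei) on a symmetric distance matrix.

    Ties in the Q-criterion are broken by the lexicographically smallest
    label pair, and negative branch lengths are clamped to zero, so the
    output is deterministic. The unrooted NJ tree is returned rooted at the
    midpoint of the final join (use the outgroup convention in
    :func:`build_backbone` for a biologically meaningful root).
    """
    D = np.asarray(D, dtype=float)
    n = len(labels)
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if np.any(D < 0):
        raise ValueError("negative distances")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix is not symmetric")
    if not np.allclose(np.diag(D), 0):
        raise ValueError("distance matrix diagonal must be zero")

    M = D.copy()
    act_labels = list(labels)
    act_nodes = [TreeNode(l) for l in labels]
    fresh = 0
    while len(act_labels) > 2:
        m = len(act_labels)
        r = M.sum(axis=1)
        Q = (m - 2) * M - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(Q <= qmin + 1e-9)
        i, j = min(((int(a), int(b)) for a, b in cand if a < b),
                   key=lambda p: tuple(sorted((act_labels[p[0]], act_labels[p[1]]))))
        dij = M[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        ci, cj = act_nodes[i], act_nodes[j]
        ci.length = max(li, 0.0)
        cj.length = max(lj, 0.0)
        new = TreeNode(None)
        new.add_child(ci)
        new.add_child(cj)
        dnew = 0.5 * (M[i, :] + M[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        M2 = np.empty((len(keep) + 1, len(keep) + 1))
        M2[:-1, :-1] = M[np.ix_(keep, keep)]
        M2[-1, :-1] = M2[:-1, -1] = np.maximum(dnew[keep], 0.0)
        M2[-1, -1] = 0.0
        M = M2
        fresh += 1
        act_labels = [act_labels[k] for k in keep] + [f"\x00nj{fresh}"]
        act_nodes = [act_nodes[k] for k in keep] + [new]

    root = TreeNode(None)
    a, b = act_nodes
    half = max(M[0, 1] / 2.0, 0.0)
    a.length = b.length = half
    root.add_child(a)
    root.add_child(b)
    return CellLineageTree(root)


def _reroot_at(tree: CellLineageTree, new_root: TreeNode) -> CellLineageTree:
    """Reorient the tree so that ``new_root`` becomes the root; a former root
    left with a single child is spliced out."""
    path = []
    n: TreeNode | None = new_root
    while n is not None:
        path.append(n)
        n = n.parent
    for child, par in zip(path[:-1], path[1:]):
        par.children.remove(child)
    for child, par in zip(path[:-1], path[1:]):
        par.length = child.length
        child.add_child(par)
    new_root.parent = None
    new_root.length = 1.0
    old_root = path[-1]
    if len(old_root.children) == 1 and old_root.parent is not None:
        child = old_root.children[0]
        grand = old_root.parent
        grand.children[grand.children.index(old_root)] = child
        child.parent = grand
        child.length += old_root.length
    return CellLineageTree(new_root)


def build_backbone(bm: BarcodeMatrix) -> tuple[CellLineageTree, UniqueBarcodeIndex]:
    """Step A: unique-barcode NJ backbone, rooted via an unedited outgroup.

    With a single unique barcode the backbone is a single leaf; the local
    search downstream resolves the whole clone.
    """
    index = collapse_unique_barcodes(bm)
    if index.k == 1:
        leaf = TreeNode(index.barcodes[0])
        return CellLineageTree(leaf), index
    root_bc = UNMUTATED * bm.site_count if all(
        len(t) == 1 for b in index.barcodes for t in _tokens(b)) else "\t".join(
        [UNMUTATED] * bm.site_count)
    labels = index.barcodes + [_OUTGROUP]
    D = hamming_matrix(index.barcodes + [root_bc])
    tree = neighbor_joining(D, labels)
    out = next(n for n in tree.postorder() if n.name == _OUTGROUP)
    tree = _reroot_at(tree, out.parent)
    out.detach()
    root = tree.root
    if len(root.children) == 1:
        root.children[0].parent = None
        tree = CellLineageTree(root.children[0])
    return tree, index


def _tokens(b: str) -> list[str]:
    return b.split("\t") if "\t" in b else list(b)
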