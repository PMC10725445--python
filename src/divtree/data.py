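"""Domain types and file I/O for barcode matrices, expression matrices and trees.

The central objects are:

* :class:`BarcodeMatrix` — cells x target-site character matrix. Each entry
  is ``"0"`` (unedited), an opaque mutation token, or ``"-"`` (dropped out).
  Column order is the physical order of target sites on the recorder, which
  matters for excision dropout.
* :class:`ExpressionMatrix` — cells x genes, non-negative values.
* :class:`CellLineageTree` — rooted tree over cells (leaves) and division
  events (internal nodes).
* :class:`CellStateTree` — rooted directed tree over discrete cell states;
  supplies the graph geodesic and state MRCAs used by the likelihood.

Newick parsing is delegated to dendropy; serialization is a direct recursive
write so internal node labels (used for state labels) round-trip exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import dendropy
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

UNMUTATED = "0"
DROPOUT = "-"


class TreeNode:
    """A node of a rooted tree; children are ordered but order carries no meaning."""

    __slots__ = ("name", "children", "parent", "length", "state", "barcode")

    def __init__(self, name: str | None = None, length: float = 1.0):
        self.name = name
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None
        self.length = length
        self.state: str | None = None
        self.barcode: str | None = None

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    def detach(self) -> "TreeNode":
        if self.parent is not None:
            self.parent.children.remove(self)
            self.parent = None
        return self

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover
        return f"TreeNode({self.name!r}, {len(self.children)} children)"


def _traverse_post(node: TreeNode) -> Iterator[TreeNode]:
    stack = [(node, False)]
    while stack:
        n, expanded = stack.pop()
        if expanded:
            yield n
        else:
            stack.append((n, True))
            for c in reversed(n.children):
                stack.append((c, False))


def _traverse_pre(node: TreeNode) -> Iterator[TreeNode]:
    stack = [node]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(reversed(n.children))


class _RootedTree:
    """Shared machinery for the two tree flavours."""

    def __init__(self, root: TreeNode):
        self.root = root

    def postorder(self) -> Iterator[TreeNode]:
        return _traverse_post(self.root)

    def preorder(self) -> Iterator[TreeNode]:
        return _traverse_pre(self.root)

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def n_leaves(self) -> int:
        return sum(1 for n in self.postorder() if n.is_leaf)

    @property
    def is_binary(self) -> bool:
        return all(len(n.children) in (0, 2) for n in self.postorder())

    def copy(self):
        mapping: dict[int, TreeNode] = {}
        for n in self.postorder():
            m = TreeNode(n.name, n.length)
            m.state, m.barcode = n.state, n.barcode
            for c in n.children:
                m.add_child(mapping[id(c)])
            mapping[id(n)] = m
        return type(self)(mapping[id(self.root)])

    def to_newick(self, branch_lengths: bool = True) -> str:
        def fmt(n: TreeNode) -> str:
            label = n.name or ""
            bl = f":{n.length:g}" if branch_lengths else ""
            if n.is_leaf:
                return f"{label}{bl}"
            inner = ",".join(fmt(c) for c in n.children)
            return f"({inner}){label}{bl}"

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str):
        dt = dendropy.Tree.get(data=newick, schema="newick",
                               suppress_internal_node_taxa=False)
        seen: set[str] = set()

        def convert(dn) -> TreeNode:
            label = None
            if dn.taxon is not None:
                label = dn.taxon.label
            elif dn.label is not None:
                label = dn.label
            node = TreeNode(label, dn.edge.length if dn.edge.length is not None else 1.0)
            for dc in dn.child_nodes():
                node.add_child(convert(dc))
            if node.is_leaf:
                if label is None:
                    raise ValueError("unlabeled leaf in Newick input")
                if label in seen:
                    raise ValueError(f"duplicate leaf label {label!r}")
                seen.add(label)
            return node

        return cls(convert(dt.seed_node))

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    @classmethod
    def read(cls, path):
        with open(path) as fh:
            return cls.from_newick(fh.read())


class CellLineageTree(_RootedTree):
    """Rooted division tree; leaves are observed cells.

    Nodes may carry a ``state`` (cell-state label) and a ``barcode``
    (character string over the barcode alphabet).
    """


class CellStateTree(_RootedTree):
    """Rooted directed tree of cell-state labels (root -> leaves).

    Provides the directed graph geodesic (``+inf`` when no directed path
    exists) and the most recent common ancestor of two states.
    """

    def __init__(self, root: TreeNode):
        super().__init__(root)
        self._index()

    def _index(self) -> None:
        self._nodes: dict[str, TreeNode] = {}
        self._depth: dict[str, int] = {}
        self._parent: dict[str, str | None] = {}
        for n in self.preorder():
            if n.name is None:
                raise ValueError("every state-tree node must carry a state label")
            if n.name in self._nodes:
                raise ValueError(f"duplicate state label {n.name!r}")
            self._nodes[n.name] = n
            if n.parent is None:
                self._depth[n.name] = 0
                self._parent[n.name] = None
            else:
                self._depth[n.name] = self._depth[n.parent.name] + 1
                self._parent[n.name] = n.parent.name

    @property
    def states(self) -> list[str]:
        return [n.name for n in self.preorder()]

    def _check(self, s: str) -> None:
        if s not in self._nodes:
            raise KeyError(f"unknown state {s!r}")

    def ancestor_path(self, s: str) -> list[str]:
        """States from the root down to ``s`` inclusive."""
        self._check(s)
        path = []
        cur: str | None = s
        while cur is not None:
            path.append(cur)
            cur = self._parent[cur]
        return path[::-1]

    def geodesic(self, s1: str, s2: str) -> float:
        """Length of the directed path s1 -> s2; ``math.inf`` if s2 is not a
        descendant (or equal) of s1."""
        self._check(s1)
        self._check(s2)
        d = self._depth[s2] - self._depth[s1]
        if d < 0:
            return math.inf
        cur = s2
        for _ in range(d):
            cur = self._parent[cur]
        return float(d) if cur == s1 else math.inf

    def mrca(self, s1: str, s2: str) -> str:
        self._check(s1)
        self._check(s2)
        a, b = s1, s2
        while self._depth[a] > self._depth[b]:
            a = self._parent[a]
        while self._depth[b] > self._depth[a]:
            b = self._parent[b]
        while a != b:
            a, b = self._parent[a], self._parent[b]
        return a


@dataclass
class BarcodeMatrix:
    """Cells x target-site character matrix.

    ``entries[i][j]`` is the symbol of cell i at site j: ``"0"`` unedited, a
    mutation token, or ``"-"`` for excision dropout. Mutation tokens are
    opaque and compared by equality only.
    """

    cell_ids: list[str]
    entries: list[list[str]]

    def __post_init__(self):
        if not self.entries:
            raise ValueError("empty barcode matrix")
        m = len(self.entries[0])
        if m < 1:
            raise ValueError("barcode matrix needs at least one target site")
        for cid, row in zip(self.cell_ids, self.entries):
            if len(row) != m:
                raise ValueError(f"ragged row for cell {cid!r}: "
                                 f"expected {m} entries, got {len(row)}")
        if len(self.cell_ids) != len(self.entries):
            raise ValueError("cell_ids / entries length mismatch")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def site_count(self) -> int:
        return len(self.entries[0])

    def row(self, cell_id: str) -> list[str]:
        return self.entries[self.cell_ids.index(cell_id)]

    def barcode_strings(self) -> list[str]:
        """One joined string per cell; tokens are tab-separated internally only
        when a token is longer than one character."""
        if all(len(s) == 1 for r in self.entries for s in r):
            return ["".join(r) for r in self.entries]
        return ["\t".join(r) for r in self.entries]

    @classmethod
    def from_strings(cls, cell_ids: Iterable[str], barcodes: Iterable[str]) -> "BarcodeMatrix":
        rows = [list(b) if "\t" not in b else b.split("\t") for b in barcodes]
        return cls(list(cell_ids), rows)


@dataclass
class ExpressionMatrix:
    """Cells x genes non-negative expression values (counts or log-normalized)."""

    cell_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError("values shape does not match cell/gene ids")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        idx = [self.gene_ids.index(g) for g in genes]
        return ExpressionMatrix(self.cell_ids, list(genes), self.values[:, idx])

    def subset_cells(self, cells: list[str]) -> "ExpressionMatrix":
        idx = [self.cell_ids.index(c) for c in cells]
        return ExpressionMatrix(list(cells), self.gene_ids, self.values[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)


@dataclass
class LikelihoodParams:
    """Weights and kernel parameters of the tree log-likelihood.

    lambda1 weights the asymmetric-division term, lambda2 the
    neighbor-distance term. ``p_asym`` is the probability that a division is
    asymmetric. ``sigma`` is the RBF bandwidth of the diffusion kernel
    ("auto" = median pairwise distance). ``inf_geodesic_penalty`` is added to
    the log-likelihood for each edge whose state transition has no directed
    path on the state tree.
    """

    lambda1: float = 10.0
    lambda2: float = 1.0
    p_asym: float = 0.8
    sigma: float | str = "auto"
    inf_geodesic_penalty: float = -50.0

    def __post_init__(self):
        if not (0.0 < self.p_asym < 1.0):
            raise ValueError("p_asym must lie in (0, 1)")
        if self.sigma != "auto" and not (isinstance(self.sigma, (int, float)) and self.sigma > 0):
            raise ValueError("sigma must be positive or 'auto'")


StateAssignment = dict  # cell or node name -> state label


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_barcodes(path, dialect: str = "auto") -> BarcodeMatrix:
    """Read a barcode character matrix from CSV/TSV.

    First column holds cell ids, remaining columns one target site each.
    All entries are read as strings.
    """
    sep = {"auto": None, "csv": ",", "tsv": "\t"}[dialect]
    df = pd.read_csv(path, sep=sep, engine="python", dtype=str, index_col=0)
    if df.empty:
        raise ValueError("empty barcode matrix")
    return BarcodeMatrix([str(i) for i in df.index],
                         df.to_numpy().tolist())


def write_barcodes(bm: BarcodeMatrix, path, sep: str = ",") -> None:
    df = pd.DataFrame(bm.entries, index=bm.cell_ids,
                      columns=[f"site{j}" for j in range(bm.site_count)])
    df.index.name = "cell_id"
    df.to_csv(path, sep=sep)


def read_expression(path, cells_path=None, genes_path=None) -> ExpressionMatrix:
    """Read expression from dense CSV (cells x genes, first column cell id)
    or MatrixMarket ``.mtx`` with row/column label files."""
    path = str(path)
    if path.endswith(".mtx"):
        if cells_path is None or genes_path is None:
            raise ValueError("MTX input needs cells_path and genes_path label files")
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        cells = [l.strip() for l in open(cells_path) if l.strip()]
        genes = [l.strip() for l in open(genes_path) if l.strip()]
        return ExpressionMatrix(cells, genes, np.asarray(mat, dtype=float))
    df = pd.read_csv(path, index_col=0)
    return ExpressionMatrix([str(i) for i in df.index],
                            [str(c) for c in df.columns],
                            df.to_numpy(dtype=float))


def write_expression(em: ExpressionMatrix, path) -> None:
    em.to_frame().rename_axis("cell_id").to_csv(path)


def read_newick(path, kind: str = "lineage"):
    """Read a Newick tree as a :class:`CellLineageTree` (``kind="lineage"``)
    or :class:`CellStateTree` (``kind="state"``)."""
    cls = {"lineage": CellLineageTree, "state": CellStateTree}[kind]
    return cls.read(path)


def write_newick(tree: _RootedTree, path) -> None:
    tree.write(path)


def read_states(path) -> StateAssignment:
    """Read a two-column CSV (cell_id, state) into a state assignment."""
    df = pd.read_csv(path, dtype=str)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_states(sa: StateAssignment, path) -> None:
    pd.DataFrame({"cell_id": list(sa), "state": [sa[c] for c in sa]}).to_csv(path, index=False)


def validate_alphabet(bm: BarcodeMatrix, tokens: set[str] | None = None) -> None:
    """Check that entries use only the reserved symbols plus known mutation
    tokens (if a token set is given)."""
    for cid, row in zip(bm.cell_ids, bm.entries):
        for s in row:
            if s in (UNMUTATED, DROPOUT):
                continue
            if tokens is not None and s not in tokens:
                raise ValueError(f"cell {cid!r}: symbol {s!r} outside declared alphabet")
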