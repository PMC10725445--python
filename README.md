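# divtree

Reconstruction of single-cell division trees from paired CRISPR lineage
barcodes and gene expression.

CRISPR lineage recorders accumulate irreversible edits at a small array of
target sites as cells divide, but in real experiments many cells end up with
the *same* barcode: edits are biased toward hot sites and popular outcomes,
and simultaneous cuts excise the targets in between (dropout). The barcode
alone therefore leaves large clones of cells unresolved, and identical edits
arising independently on different lineages (homoplasy) can group unrelated
cells together. `divtree` resolves those clones with the cells' gene
expression, under an asymmetric-division model of differentiation.

## Method

Given a barcode character matrix **X** (N cells × M target sites, entries
`0` = unedited, token = edit, `-` = dropped out) and an expression matrix,
the pipeline is:

* **A — backbone.** Collapse identical barcodes into K unique barcodes and
  build a Hamming-distance Neighbor-Joining tree over them, rooted via an
  artificial unedited outgroup (the recorder starts all-`0` at the root).
* **B — states.** k-means (default k = 7) on the first 20 PCs of the
  top-100 highly variable genes gives discrete cell states; a minimum
  spanning tree over cluster centroids, directed away from a chosen root
  state, gives the cell-state tree. Both can instead be supplied as inputs.
* **C — clone subtrees.** For each clone, find the binary subtree 𝒯
  maximizing

  ℒ(𝒯) = ℒ_E(𝒯) + λ₁·ℒ_ad(𝒯) + λ₂·ℒ_nd(𝒯),  λ₁ = 10, λ₂ = 1,

  where ℒ_E scores each edge's parent→child state transition by the
  empirical probability of its graph-geodesic length on the state tree
  (−50 per edge with no directed path), ℒ_ad gives each division
  log p_a if the daughters' states differ and log(1 − p_a) otherwise
  (p_a = 0.8), and ℒ_nd adds the log diffusion-map transition probability
  between the expression profiles of each sibling leaf pair. Ancestral
  states come from a bottom-up pass (equal children keep their state,
  unequal children take the MRCA on the state tree). The search is hill
  climbing with random-subtree-swap proposals and random restarts; each
  restart is budgeted min(C(n), max_iter) proposals, with C(n) the nth
  Catalan number and max_iter = 500.
* **D — reattachment.** Each backbone leaf is replaced by its clone's
  optimized subtree.

The package also provides the evaluation stack: normalized Robinson–Foulds
distance, Nye similarity (matched-split Jaccard scores), clustering
information distance, and the barcode-quality statistics Q_r (fraction of
true-tree edges carrying a mutation) and Q_h (fraction of edges whose new
mutations all recur elsewhere), plus a simulator producing ground-truth
division trees with realistically biased, dropout-prone barcodes and
state-dependent expression.

## Worked example

```sh
divtree simulate --generations 7 --mu 0.1 --seed 1 --out-prefix run1
# 128 cells; sharing fraction 0.930
divtree backbone --barcodes run1.barcodes.csv --out backbone.nwk
# 18 unique barcodes over 128 cells
divtree reconstruct --barcodes run1.barcodes.csv --expr run1.expr.csv \
    --state-tree run1.state_tree.nwk --states run1.states.csv \
    --seed 1 --out rec.nwk
divtree evaluate --true run1.true_tree.nwk --pred rec.nwk
divtree quality --tree run1.true_tree.nwk --barcodes run1.barcodes_all.csv
```

The simulated 128-cell dataset is deliberately hard: 93% of cells share a
barcode with at least two others, so only 18 of 128 cells are distinguishable
from barcodes alone. `evaluate` prints

```json
{"rf": 0.872, "nye": 0.372631085710798, "cid": 0.6317206361951706}
```

— the reconstruction recovers ~13% of the true splits exactly (RF 0.872)
and scores 0.37/0.63 on the partial-credit metrics, far better than the
barcode-only ceiling: `quality` reports `Q_r = 0.110`, meaning only 11% of
the true tree's edges carry any mutation at all, so ~89% of splits are
invisible to any barcode-only method on this dataset.

Library use mirrors the CLI:

```python
import divtree as dv

gt = dv.simulate(dv.SimConfig(n_generations=10, mu=0.1, dropout=True, seed=0))
tree = dv.reconstruct(gt.barcodes, gt.expression,
                      state_tree=gt.state_tree, leaf_states=gt.leaf_states,
                      cfg=dv.SearchConfig(seed=0))
print(dv.rf_distance(gt.tree, tree))
```

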