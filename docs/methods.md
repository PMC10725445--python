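# Methods

## Problem setting

A CRISPR lineage recorder is an array of M editable target sites carried by
every cell. Each division can irreversibly edit unedited sites; when two or
more edits land in the same division, the sites between the outermost cuts
are excised and read out as missing (`-`), heritably. The observed data are
the leaf barcodes (N cells × M characters) and each cell's transcriptome.
The goal is the rooted binary division tree over the N cells.

Because edits are biased toward hot sites and frequent outcomes, and because
excision collapses diversity, many cells share identical barcodes ("clones")
and identical edits recur on unrelated lineages (homoplasy). Barcodes alone
cannot order cells within a clone; expression can, because cell state is
inherited with occasional asymmetric transitions.

## Reconstruction pipeline

**Backbone (step A).** Identical barcodes are collapsed; a Neighbor-Joining
tree over the K unique barcodes is built from Hamming distances. `-` is a
first-class symbol matching only `-`: excision dropout is heritable, so
shared dropout is lineage signal. Rooting uses an artificial all-`0`
outgroup (NJ is run on K+1 taxa, the tree is rooted on the outgroup edge and
the outgroup deleted), reflecting that the recorder starts unedited at the
root. NJ ties on the Q-criterion are broken by the lexicographically
smallest label pair and negative branch lengths are clamped to zero, so the
backbone is deterministic.

**States (step B).** If no state tree is supplied: log1p-transform, keep the
100 most variable genes, project on 20 PCs (full-SVD PCA, deterministic),
k-means with k = 7, then a minimum spanning tree over cluster centroids
directed away from a root state (named directly or through a root cell).
The MST over centroids is the lineage-structure core of MST-based trajectory
methods; pseudotime/principal-curve refinement is not needed because only
the rooted tree of state labels enters the likelihood. Supplying a known
state tree and state labels ("true state tree" mode) bypasses this entirely
and is the recommended path when they are available.

**Likelihood.** A candidate tree T over one clone's cells is scored as
L = L_E + λ₁·L_ad + λ₂·L_nd with λ₁ = 10, λ₂ = 1.

* Ancestral states: post-order; equal children propagate their state,
  unequal children take their MRCA on the state tree (two states on one
  differentiation path resolve to the earlier one, which is their MRCA).
* L_E: every edge's parent→child transition has a graph-geodesic length on
  the state tree (the number of directed steps; infinite if no directed
  path). The probability of each observed length is estimated empirically
  from the finite-geodesic edges of the tree being scored — during clone
  search, from that clone's subtree only, since clones are optimized
  independently; a whole-tree mode exists for reporting. Each
  infinite-geodesic edge adds a flat −50 to the log-likelihood. Note that
  trees whose internal states come from the MRCA rule have no infinite
  edges; the penalty matters for externally supplied state annotations.
* L_ad: each division contributes log p_a if the daughters' states differ
  and log(1 − p_a) if they agree, with p_a = 0.8 — asymmetric divisions are
  the norm during differentiation. Multi-step asymmetry still counts once
  (the event is binary same/different). A naive plug-in estimator of p_a
  (fraction of discordant cherries) is provided but flagged experimental;
  all defaults use 0.8.
* L_nd: for each sibling leaf pair, the log diffusion-map transition
  probability between their expression profiles. The kernel is an RBF on
  log1p expression of the top-100 HVGs; the bandwidth σ defaults to the
  median pairwise distance within the cell set under consideration (a
  standard heuristic; the clone's own cells during search). The transition
  matrix is density-normalized (each row sums to 1 over the other cells)
  and is asymmetric; sibling pairs are unordered, so the two directions are
  averaged before taking the log (an ordered variant is available).
  Probabilities are floored at 1e-300 before the log so distant outliers
  produce large finite penalties rather than −inf.

**Search (step C).** Clones of 1–3 cells are solved directly (3 cells:
all three rooted topologies are scored). Larger clones use hill climbing:
uniformly random rooted binary initialization (sequential random
attachment), random-subtree-swap proposals (two non-nested non-root nodes
exchange positions — binarity and the leaf set are preserved), strict
acceptance (ties keep the incumbent, so a run is reproducible from its
seed), a local optimum declared after 100 consecutive rejections, and up to
3 additional random restarts. Each restart's proposal budget is
min(C(n), max_iter) with C(n) the nth Catalan number (computed exactly with
big integers) and max_iter = 500 — small clones get only as many proposals
as their topology space warrants. The best tree across restarts is
returned. The budget is per restart: under a shared total budget a 4-leaf
clone would receive 14 proposals for its 15 topologies and the search could
not reliably reach the optimum that exhaustive enumeration finds.

Clones are processed in lexicographic barcode order with per-clone seeds
derived from the global seed (CRC32 of the barcode), so serial and parallel
execution orders give identical results.

**Reattachment (step D).** Each backbone leaf is replaced by its clone's
subtree root; singleton clones remain leaves. The final tree's leaves are
exactly the N input cells.

## Evaluation metrics

All tree metrics operate on non-trivial splits (both sides ≥ 2 leaves),
deduplicated in the unrooted sense; multifurcating trees contribute their
splits as-is.

* **RF distance** |S₁ △ S₂| / (|S₁| + |S₂|) ∈ [0, 1]; 0 iff the split sets
  coincide. For two fully resolved binary trees this equals the usual
  normalization by 2(n−3).
* **Nye similarity**: each split pair is scored
  max{min(a_ll, a_rr), min(a_rl, a_lr)} from the four side-pairing Jaccard
  ratios; splits are aligned by maximum-weight bipartite matching
  (Hungarian algorithm) and the matched sum is divided by the larger split
  count so the score lands in [0, 1] (the raw sum is also reported).
* **Clustering information distance**: each split is a 2-block clustering
  of the leaves; matched splits (again Hungarian, on mutual information)
  contribute their MI, and the distance is
  (H₁ + H₂ − 2·I*) / (H₁ + H₂), where H is the sum of split entropies
  (natural log). 0/0 is defined as 0 so two star trees are identical.

Barcode quality is computed on a true tree annotated with ancestral
barcodes. Q_r is the fraction of edges on which the barcode changes — an
edge with no mutation can never be recovered by barcodes, so Q_r upper
bounds barcode-only split recovery. Q_h is the fraction of edges whose
newly introduced mutations — identified as (site, token) pairs, dropout
sites excluded — are all also introduced on other edges. Edges introducing
no mutation are excluded from the numerator: a literal reading of the
set-inclusion definition would count every mutation-free edge (the empty
set is a subset of anything), which contradicts the notion of a homoplasy
edge; that literal variant is available behind a flag for comparison.

## Synthetic data generator

The generator emulates a recorder experiment end to end and is the test bed
for every desk-scale claim.

* **Division tree**: full binary, d generations (default 10 → 1024 leaves).
* **States**: the root carries the state-tree root; at each division, with
  probability p_a = 0.8 (and only if the current state has children on the
  state tree) one uniformly chosen daughter advances to a uniformly chosen
  child state. The default state tree is a balanced binary tree with 52
  states (depth 5), emulating a finely discretized differentiation
  hierarchy; with a shallow state tree, states exhaust after a couple of
  divisions and nearly all divisions become symmetric, which is neither
  realistic nor the regime the method addresses.
* **Barcodes**: per division, an unedited site j mutates with probability
  μ_j; outcomes are drawn from a geometric distribution over 20 tokens
  (weight ∝ 0.7^rank). Site propensities follow the same geometric law,
  rescaled to mean μ and spread over array positions with a golden-ratio
  low-discrepancy permutation — hot sites dominate editing, as in real
  recorders, but are scattered along the array so that simultaneous cuts
  can excise substantial stretches. When ≥ 2 edits occur in one division,
  all sites strictly between the outermost new edits become `-`,
  heritably. Mutated and dropped sites never change again (`-` is
  absorbing). Random draws are fixed-length per division, so dropout
  on/off comparisons are paired on identical edit streams. An optional
  capture-dropout rate masks whole leaf barcodes.
* **Expression**: every state-tree edge owns one marker gene, expressed at
  `mean_separation` (default 5) in all states at or below it over a
  baseline of 1; the remaining genes are flat background. State means thus
  embed the state tree as an exact tree metric (squared centroid distance ∝
  path length), giving the continuous manifold structure the state
  inference relies on. Cells add i.i.d. Gaussian noise (default sd 1),
  clipped at zero; a Poisson count model is optional. This is deliberately
  not a kinetic transcription model: it reproduces the features downstream
  code consumes (state-separable clusters, tree-shaped centroid geometry,
  state-dependent sibling similarity) and nothing else, so passing tests
  say nothing about, e.g., bursty counts or batch structure in real data.

## Problem sizes used in the test suite

Simulator statistics run at the published conditions (1024 cells, 16 sites,
10 seeds for sharing fractions, 5 per rate for the homoplasy sweep). The
reconstruction-benefit check runs 10 seeded 1024-cell datasets (μ = 0.1,
dropout) and compares against a random resolution of the same backbone with
a one-sided paired Wilcoxon test; the mutation-rate trend uses 5 seeds per
rate at 1024 cells. Search-vs-enumeration equivalence uses 100 clones of
4–6 cells against exhaustive topology scoring (15/105/945 topologies), with
restarts = 10 and patience = 20 so the restart mechanism is actually
exercised within the small Catalan budgets.

## Numerical and degenerate-input choices

* All-identical barcodes (K = 1): the backbone is a single leaf and the
  whole dataset is one clone.
* An all-`0` barcode already present among the unique barcodes coexists
  with the artificial outgroup (labels differ; the outgroup is deleted
  after rooting).
* Empty transition table (every edge infinite): L_E is the penalty times
  the edge count.
* σ = "auto" with coincident points (median distance 0) falls back to 1.
* k-means uses 10 seeded initializations; scikit-learn guarantees no empty
  clusters.
* PCA uses the full SVD solver; signs of components may differ across
  platforms but none of the downstream quantities depend on them.

## Known limitations

* The generator's edit-outcome and site-propensity laws are a two-parameter
  stand-in for real indel spectra; it reproduces the direction and rough
  magnitude of the dropout-driven diversity collapse, but not every
  published one-dataset statistic (see the acceptance output: the
  no-dropout sharing fraction runs high and the homoplasy ceiling low
  relative to the reference values).
* Q_h depends on the fraction of edges that mutate at all, which for 16
  irreversible sites over 10 generations is intrinsically small near the
  leaves; comparisons across recorder designs should hold M and d fixed.
* Expression carries state information only — cells of the same state are
  exchangeable up to noise — so within-state placement inside a clone is
  resolved essentially by the neighbor-distance term acting on noise. Real
  data with clone-specific expression would provide more signal than the
  simulator does.
* The search optimizes clones independently; errors in the backbone (from
  homoplasy) cannot be repaired downstream, which is the documented cost of
  avoiding whole-tree search.
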