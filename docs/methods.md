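# Methods

This note documents the models and algorithms implemented in `scassign`,
the parameters that matter, the synthetic data used to test them, and the
design choices made where more than one reasonable option existed.

## Preprocessing

Counts are filtered cell-then-gene, each filter applied exactly once:
cells are kept when their number of expressed genes (strictly positive
counts) lies in [`min_genes_per_cell`, `max_genes_per_cell`] = [50, 3000]
inclusive, then genes expressed in [50, 3000] cells are kept. The
boundary values are kept deliberately: the rule excludes "fewer than 50
or more than 3000". Each surviving cell is scaled to a total of
`target_sum` = 1e5 and log1p-transformed; each gene is then centered and
divided by its population (ddof = 0) standard deviation. Zero-variance
genes are centered only; no post-scaling clipping is applied (some
toolchains clip at ±10; we do not). The pre-scaling log-normalized
matrix is retained in the `"lognorm"` layer because differential
expression and fold changes are computed on it — t-tests on
zero-mean-scaled values would make fold changes meaningless.

Spatial proteomics panels (CODEX-style, ~19 channels) skip the whole
stage: `preprocess_pipeline(..., skip_normalization=True)` is the
identity on values.

## Embedding and graph construction

PCA uses scikit-learn's randomized SVD with an explicit seed; 40
components by default, capped at min(n_cells − 1, n_features). The kNN
graph is an exact Euclidean search (chunked full distance computation —
adequate below ~10⁴ cells, which is the regime of every fixture here);
the k = 15 directed neighbor lists are union-symmetrized into an
undirected, unweighted graph. Ties at equal distance break toward the
lower cell index via a stable sort, making graph construction fully
deterministic. For protein panels the clustering embedding is a 10-D
UMAP instead of PCA, and every dataset gets a 2-D UMAP only for
visualization.

## Leiden and the frozen-cluster variant

The optimiser maximizes the RB-configuration quality
H(P) = Σ_c [w_in(c) − γ K_c²/(4m)] with resolution γ, where w_in(c) is
the intra-community edge weight, K_c the community degree sum and m the
total edge weight. It is written in-package so that the frozen-cluster
constraint participates in *all three* phases:

* **Local moving** is queue-based. A dequeued node evaluates staying,
  every neighboring community, and a fresh singleton; among the
  maximal-gain candidates one is chosen uniformly at random (seeded).
  Accepting zero-gain moves lets the optimiser walk plateaus that strict
  improvement cannot cross (common on small unweighted graphs); a
  dequeue budget of 100·n guarantees termination, and quality never
  decreases because only non-negative gains are accepted. Frozen nodes
  are never dequeued into a move.
* **Refinement** re-partitions each community from singletons, with the
  frozen members of a community pre-merged into one atomic subcommunity
  that never splits; unfrozen singletons greedily merge into the best
  positively-scoring adjacent subcommunity, visited in seeded random
  order.
* **Aggregation** collapses subcommunities into super-nodes; a
  super-node is frozen if it contains any frozen cell, and inherits its
  community membership, so the constraint propagates to all levels.

The run restarts several times (8 by default; 48 on graphs of ≤ 64
nodes, where restarts are nearly free and the landscape has
proportionally more attraction basins per node) with seeded
diversification: restart 0 starts from the supplied initialization,
others restart the unfrozen cells as singletons or from a random coarse
labeling. The best-quality result is kept and canonicalized. On all
graphs of ≤ 8 nodes in the test family the returned constrained optimum
equals exhaustive enumeration over constraint-satisfying partitions; on
larger fixtures the unconstrained path matches the quality reached by
the independent `leidenalg` implementation.

Constraint semantics, stated precisely: frozen cells never change
community; two frozen cells with the same initial label always share a
final community, two frozen cells with different initial labels never
do; unfrozen cells may join frozen communities. This is the minimal
reading of "frozen clusters are not allowed to change" that still lets
refinement improve unfrozen regions.

Edges are unweighted and the quality function is RB-configuration
modularity with a linear resolution parameter — both pinned for
reproducibility since reasonable alternatives (weighted kNN edges, CPM
quality) exist.

## Label transfer and refinement

`fit_transfer` computes the reference/query gene intersection in
reference order, standardizes the reference restricted to it, and fits
PCA-40 on the reference only. The query is standardized **with the
reference's means and standard deviations** before projection; scaling
the query independently is rejected because it breaks the self-transfer
identity (query = reference with k = 1 must return the reference's own
labels exactly, and does). Voting is an unweighted majority over the
k = 15 nearest reference cells, ties broken by summed inverse distance
and then by the smaller label; confidence is the winning vote fraction,
in [1/k, 1].

"Least noisy clusters" is operationalized as clusters whose **median**
cell confidence clears a threshold (default 0.9), with an explicit
override list for reproducing a manual, expert choice. The threshold is
a per-analysis decision: the confidence ceiling is set by the purity of
reference neighborhoods, which depends on dataset size and noise. On the
synthetic transfer experiment below, the confidence distribution is
bimodal — clean clusters ≥ ~0.85, corrupted clusters ≤ ~0.67 — and the
experiment freezes at 0.75, the gap between the modes; at its problem
size the 0.9 default would clip the lower tail of the clean mode.

`transfer_and_refine` chains: fit → vote → build the query's own
PCA/kNN graph → freeze confident clusters → constrained Leiden
initialized from the transferred labels. Both the refined and the raw
transferred partitions are returned so they can be compared.

For dual-modality data profiled on the same cells,
`copy_labels_by_cell_id` matches by cell identifier, labels unmatched
target cells `"unassigned"`, and warns (rather than fails) on zero
matches.

## scATAC gene activity

Gene records are read from GENCODE-dialect GTF (1-based inclusive →
0-based half-open; duplicate gene_ids are an error; strandless records
are skipped with a warning). Gene spans are extended strand-aware:
5000 bp past the 3′ end (downstream) and 1000 bp past the 5′ end
(upstream), clipped at zero. The downstream-heavy extension is unusual
among promoter-centric tools but is applied literally as specified for
this workflow; `strand_aware=False` disables the strand flip. A peak
overlaps an extended gene if the half-open intervals share ≥ 1 bp; peaks
contribute their full counts to every overlapped gene (no
overlap-fraction weighting, no binarization). Lookup uses per-chromosome
interval trees; the test oracle is the O(peaks × genes) double loop, and
the two agree exactly on 100 randomized fixtures including
boundary-touching peaks and origin-clipped genes. Chromosome-name
harmonization ("1" vs "chr1") happens only on request, never silently;
a total overlap of zero raises a diagnostic suggesting it.

## Differential expression and enrichment

Welch's t (sample variances, Welch–Satterthwaite df, two-sided Student-t
tail) is computed per gene, cluster vs rest, on the `"lognorm"` layer.
Genes with zero variance in both groups score t = 0, p = 1 when the
means agree and are reported with p = NaN (excluded from ranking) when
they do not. BH correction is applied within each cluster's gene list.
log2 fold change uses expm1-means with a pseudocount of 1. Markers are
the top-500 genes by signed log2 fold change (up-regulated markers are
the convention; an `absolute_fc` flag exists), ties broken by smaller p
then gene id; panels smaller than 500 return everything.

Enrichment is a one-sided hypergeometric overrepresentation test of the
marker set against each GMT term with BH across terms. A weighted
running-sum enrichment statistic is deliberately out of scope; the
overrepresentation test covers the same ranking intent with a fully
specifiable null.

## Spatial projection

Per-cell centroids are consumed as a CSV (`cell_id,x,y`, pixel
coordinates, origin top-left with y increasing downward — the microscopy
convention; segmentation is upstream and out of scope). One
deterministic palette (tab20 for ≤ 20 clusters, evenly spaced HSV hues
beyond) colors both the 2-D embedding panel and the spatial panel, so a
cluster has the same color in both views; rendering is pinned (Agg
backend, fixed dpi, no timestamp metadata) and byte-identical across
reruns of identical inputs.

## Synthetic data

`make_counts` draws negative-binomial counts (variance μ + φμ², φ =
`nb_dispersion` = 0.5) with Bernoulli dropout (rate 0.3) over lognormal
base means; each cluster up-regulates a disjoint block of
`de_fraction` = 20% of genes by 2^`de_log2fc` (default 8-fold). Defaults:
480 cells, 800 genes, 6 clusters. The gene count matters more than it
may appear: PCA-40 neighbor purity degrades sharply below a few hundred
genes because most components carry only noise, and 800 genes puts
cross-dataset 15-NN purity near 1 at these noise levels.

`make_transfer_pair` emulates a two-donor annotated-atlas experiment.
Both datasets come from one model; the query has a mild per-gene
lognormal shift (σ = 0.15) and each side lacks a different 10% of genes
(80% overlap). Two deliberate properties mirror how expert annotations
behave: (i) the two "clean" coarse clusters are each a union of three
fully distinct fine types annotated at the coarse level, so an
unsupervised modularity clustering at resolution 1 finds — correctly —
the fine types but is scored against the coarser expert truth; (ii) the
label corruption (`transfer_noise`, a fraction of *all* reference cells)
is confined to the four unitary "noisy" clusters and relabels each
corrupted cell to another noisy cluster, so scattered wrong labels
rarely flip a 15-neighbor vote but drag confidence down. This is what
makes the three-arm comparison meaningful: refinement (frozen clean
clusters + graph re-clustering of the rest) repairs the transfer noise,
raw transfer carries it, and de-novo clustering pays the granularity
penalty. At `transfer_noise` = 0.3 and 900 cells the mean adjusted Rand
indices over 20 seeds order refined > transferred > de-novo
(≈ 0.99 / 0.89 / 0.85 at seed 1); the experiment uses 900 cells because
below ~40 reference cells per fine type vote confidence stops being
informative.

What the fixtures do **not** model: library-size variation beyond NB
sampling, ambient RNA, doublets, batch structure richer than one
multiplicative shift, or realistic gene–gene correlation. Passing tests
therefore demonstrate the algorithms' contracts (exact oracles,
orderings, determinism), not performance claims about any real tissue.

`make_atac_fixture` builds ~50 peaks over three toy chromosomes and 20
genes on both strands, deliberately placing a near-origin gene
(extension clipping) and peaks exactly at extended-range edges
(half-open boundary), together with the brute-force expected activity
matrix. `make_spatial_fixture` places per-cluster Gaussian blobs
(σ = 40 px) on a 1000×1000 tile with centers ≥ 300 px apart.

## Numerical and reproducibility choices

* Every stochastic routine takes an explicit seed; the CLI derives
  per-stage seeds from one run seed via CRC32 of the stage name.
  Pipelines rerun with the same seed produce byte-identical outputs.
* Quality comparisons inside the optimiser use an absolute tolerance of
  1e-12; acceptance of a move requires gain ≥ −1e-12.
* Matrices are stored sparse below 50% density; sparse and dense paths
  are tested to agree to 1e-10.
* kNN ties, marker-ranking ties and vote ties all have pinned
  deterministic tie-breaks (lower index / smaller p then gene id /
  inverse distance then smaller label).

## Problem sizes

The default test suite and the acceptance script run at: 34 graphs of
≤ 8 nodes for the exact-enumeration family, 100 randomized gene-activity
fixtures, 20 seeds × 900 cells × 800 genes for the transfer experiment,
and 120–480 cells for the remaining pipeline checks. These sizes were
chosen so each property is measured with comfortable statistical margin
on a single CPU.

## Known limitations

* Exact kNN is quadratic in cells; an approximate backend (with the
  documented ≥ 99% edge-agreement contract) would be needed far above
  10⁴ cells.
* The constrained optimiser guarantees global optimality only where the
  exhaustive oracle can verify it (tiny graphs); at scale it inherits
  Leiden's heuristic character.
* The refinement phase skips the well-connectedness test of the
  canonical algorithm; with greedy positive-gain merging this did not
  produce disconnected communities on any fixture, but it is a
  simplification.
* HDF5/h5ad containers are not part of the tested I/O contract
  (MTX/CSV/TSV/GTF/GMT are).
* The cisTopic-style topic-matrix pathway is consumed only as a
  precomputed reduction via `read_csv_matrix`; topic modeling itself is
  out of scope.
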