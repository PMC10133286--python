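# Methods

## Preprocessing

Counts are UMI-deduplicated integers, genes × cells. QC removes cells
with fewer than 200 detected genes (raw count ≥ 1), total UMI outside
[500, 30000], or a mitochondrial UMI fraction above 0.25; the generous
mitochondrial ceiling reflects the high mitochondrial load of
cardiomyocytes. Mitochondrial genes default to the case-insensitive
`MT-`/`mt-` symbol-prefix rule and can be overridden with an explicit
list. Filtering is idempotent and never touches the gene axis.

Normalisation is `log2(1 + 10000 · count / cell_total)`; the pseudocount
of 1 preserves the zero pattern exactly. An optional second step
(`regress_and_scale`) fits per-gene OLS of log expression on the
per-cell totals (`n_umi`, `n_genes`), standardises the residuals to mean
0 / unit variance per gene and clips to ±10 to bound outlier leverage.
The pipeline order is fixed QC → normalise → regress. The embedding gene
list keeps genes with ≥ 1000 summed UMIs, computed on post-QC cells
(both the threshold and the timing are configurable). Pseudobulk
profiles average expression per sample, optionally over seeded random
subsets of fixed size, to emulate bulk-like replicates for enrichment
tools.

## Sparse autoencoder

The architecture is deliberately three layers only — input genes, one
hidden embedded layer (default 10 logistic units), linear synthetic
output — so that no intermediate compression can mask rare
subpopulations. The training objective is the mean per-cell squared
reconstruction error plus `l2_weight · ‖W‖²` (default 0.001, both weight
matrices) plus a KL-divergence sparsity penalty
`β Σⱼ KL(ρ ‖ ρ̂ⱼ)` pulling each hidden unit's mean activation ρ̂ⱼ toward
ρ = 0.05 (β = 1 by default; both exposed in the config). Inputs are
min-max scaled per gene to [0, 1] for the logistic encoder; the linear
decoder maps directly back to the original expression scale, so the
reconstruction term of the loss is the same quantity the similarity
score S reports.

Optimisation is a hybrid: the decoder subproblem is quadratic given the
hidden activations, so `(W₂, b₂)` are set each step by solving the ridge
normal equations exactly (with the same `l2_weight`, plus a 1e-10
numerical floor); the encoder is updated by Adam (default learning rate
1e-3, 200 epochs, full batch up to 5000 cells and mini-batches of 256
above). The encoder initialises from the principal directions of the
scaled data (`init="pca"`, the default), which starts the hidden units
in the near-linear sigmoid regime; `init="random"` gives a
Glorot-uniform draw. All randomness (init fallback, batch order) flows
from the single config seed, and retraining with the same config and
data is bit-identical, including the per-epoch loss trace.

Reconstruction fidelity is measured by `S = (1/N) Σᵢ ‖xᵢ − yᵢ‖²` over
cells and compared with PCA reconstructions (all components or top-k).
When benchmarking raw representational capacity against PCA the
`FIDELITY_BENCHMARK` recipe is used: both regularisers off and 500
full-batch epochs at learning rate 1e-2. The two penalties intentionally
trade reconstruction error for small weights and sparse codes, and the
magnitude of the fixed `0.001‖W‖²` term relative to S depends strongly
on the data scale, so a capacity benchmark with them enabled would
measure the penalty calibration rather than the architecture. The tests
verify separately that disabling the weight penalty never worsens
converged training reconstruction.

## Clustering and annotation

Clustering operates on the 10-D embedded coordinates by default (a
config switch allows the 2-D UMAP plane instead; UMAP itself is treated
as an external dependency and used for visualisation only). Three
algorithms are interchangeable: DBSCAN (eps = 0.2, minpts = 50 — note
eps is a distance in embedding units and must be rescaled for data on a
different scale), k-means (k = 7 default), and Louvain community
detection on an unweighted Euclidean 30-nearest-neighbour graph at
resolution 1.0. On a well-separated embedding the three agree almost
perfectly (pairwise adjusted Rand ≥ 0.9 in the acceptance checks), which
is the operational evidence that the embedding, not the clustering
algorithm, carries the cell-type structure. Identical coordinates are a
degenerate geometry and always yield a single cluster.

A cluster is annotated with a cell type when *every* marker of that type
has mean expression at least `min_fold` (default 2) times its mean over
all other clusters **and** is detected in at least `min_fraction`
(default 0.25) of the cluster's cells; no qualifying type gives
"unassigned", several give "ambiguous". Fold changes are evaluated on
the de-logged scale so `min_fold` means a true fold difference in
normalised counts. These two defaults operationalise the otherwise
qualitative notion of a cluster "explicitly expressing" its markers.
Composition tables report per-category cluster proportions (columns sum
to 1) and flag a cluster exclusive to a category when ≥ 0.9 of its cells
come from it. Second-level analysis re-selects embedding genes, retrains
the autoencoder, and reclusters within one annotated cell type — the
two-level scheme that first isolates a lineage and then resolves its
subpopulations. The packaged mouse panel is Myh7/Ryr2 (cardiomyocyte),
Col1a1/Col1a2 (fibroblast), Pecam1/Kdr (endothelial), Bin2/Ifi30
(immune), Tagln (smooth muscle); the pig cardiomyocyte markers are
ACTC1, MYH7, RYR2 (ACTC1 is the sarcomeric actin gene symbol).

## Sparse linear model

`|w|` in the objective is read as the L1 norm — the sparse
support-vector formulation — which makes the fit an exact linear
program via the standard split `w = w⁺ − w⁻` with `w± ≥ 0` (the
intercept is split likewise). The LP is solved with HiGHS; degenerate
programs (e.g. identical reference groups) have multiple optima in
`(w, b)` but a unique objective value, which the tests pin against an
independently assembled reference LP. The slack cost C defaults to 1.0
and is exposed everywhere. Features are the log-normalised
(unadjusted) expression values of the gene-set members present in the
matrix; a switch selects covariate-adjusted values instead. Score
categories use strict inequalities exactly as defined: scores of
exactly ±1 are "middle".

Group comparisons are two-sided Wilcoxon rank-sum tests on per-cell
scores with significance at p < 0.01 and no multiple-testing
correction — each gene set is treated as a planned, pre-specified
comparison. Null calibration (≤ 5% of seeded same-distribution repeats
significant at α = 0.01) and power (a 2-pooled-SD shift at n = 100 per
group detected at p < 0.01) are verified in the acceptance suite.

The packaged gene sets (five cell-cycle phases and six signalling
pathways) are compact editable defaults shipped as a GMT file, not a
pinned pathway-database release; analyses meant for publication should
substitute curated lists.

## Self-training trajectory assignment

Iteration 1 fits the sparse model on the two endpoint clusters
(positive y = +1, negative y = −1) and scores every origin cell; cells
with y > τ (default 0.1) are committed to the positive endpoint, y < −τ
to the negative, the rest are inconclusive (boundary scores are
inconclusive, strict inequalities). Each subsequent iteration refits on
the endpoints merged with their committed origin cells and relabels
*all* origin cells — full relabeling is required for the fixed-point
stopping rule to be well defined, and it permits a previously committed
cell to revert. The loop stops when the label partition equals the
immediately preceding one (converged) or repeats any earlier state (a
genuine oscillation, reported as non-converged rather than silently
broken), or at `max_iterations` (default 100). Termination is guaranteed
because the partition state space is finite.

Determinism and symmetry: the inner LP is deterministic, and the
endpoint roles are canonicalised internally (the lexicographically
smaller cell-id set is always solved as "positive", with signs and
labels flipped back on output), so swapping the positive and negative
inputs yields the exactly mirrored assignment even though the LP solver
itself makes no symmetry promise between mirrored programs.

The feature space defaults to all genes of the supplied (level-2
embedding) matrix; a gene-set restriction is available for targeted
analyses.

## Cytokinesis panel and counting

Candidate genes are those with at least one GO term flagged as a
cytokinesis subprocess (under GO:0032506). For each candidate the ratio
(# flagged terms)/(# unflagged terms) is computed; genes with ratio
≤ 0.9 are filtered out, and a zero unflagged count is treated as an
infinite ratio (retained). The rule is monotone in the threshold. The
authoritative input is a pre-flattened TSV (gene, term, flag) so results
do not drift with GO releases; an optional obonet-based helper derives
the flag set from an OBO file. Applied to the full GO annotation this
rule retains ALKBH4, ANLN, AURKB, CNTROB and KLHDC8B, which ship as the
default panel; the packaged toy annotation table is a synthetic fixture
constructed so the derivation reproduces exactly this panel, not a
mirror of any full annotation release. A cell expressing at least 3 of
the 5 panel genes (value strictly above `expr_threshold`, default 0,
i.e. raw count ≥ 1) is counted cytokinetic; counts and fractions are
reported per metadata group.

## Species demultiplexing

After mapping to a combined human + pig reference, each cell carries a
human-mapped and pig-mapped UMI total (optionally restricted to a
housekeeping gene list). Calls are made per cluster on summed UMIs,
which damps low-count cells: human if the human sum is ≥ 10× the pig
sum, otherwise pig, except that clusters whose larger total is less than
3× the smaller are flagged ambiguous — the two empirical rules (≥10-fold
human dominance; per-cell pig:human ratio > 5 for pig cells, < 1 for
human cells) leave a gap, and forcing a call inside it would manufacture
certainty. Every cell inherits its cluster's call; per-cell ratio
reports (pig:human, +∞ when the human total is zero) with per-cluster
quantiles support diagnostics. Calls are invariant to uniform count
scaling.

## Synthetic data

All generators are pure functions of their spec (including the seed) and
return truth labels as sidecar tables, never embedded in matrix files.
Counts are negative binomial with variance `μ + 0.5μ²` (gene-level
dispersion 0.5 by default); library sizes are log-normal with median
5,000 UMIs and σ = 0.4, chosen to sit inside the QC window (500–30,000)
while leaving its edges reachable so the filters are actually exercised.
Cell types are planted as disjoint 20-gene marker blocks at 8-fold
elevation. The trajectory generator draws origin cells as convex
mixtures of the two endpoint mean programs, with mixture weights
centred at 0.8 toward the generating endpoint (σ = 0.06) and a 60/40
split between endpoints; endpoint programs differ in disjoint 40-gene
blocks at 6-fold elevation across 300 genes. The dual-species generator
gives pig cells pig:human ratios drawn uniformly in [6, 30] and human
cells contamination fractions from Beta(1, 20) (ratios in [0, 1),
mostly near zero), matching the separation seen in cross-species
mapping. The QC fixture constructs each violation class directly
(199 genes; 499 UMIs; 30,001 UMIs; ~26–40% mitochondrial) so planted and
realised QC status coincide.

What the generators do **not** emulate: batch effects, ambient RNA,
doublets, gene–gene correlation beyond the planted programs, and
realistic dropout structure. Passing tests on these fixtures therefore
demonstrates correctness of the algorithms under their stated
assumptions, not performance on real tissue.

## Pipeline

The runner executes any subset of the fixed stage order simulate → qc →
embed → cluster → cytokinesis → trajectory → demux from a YAML config;
unknown keys anywhere in the config are rejected before any stage runs.
One global seed fans out to per-stage seeds by stable SHA-256 hashing
(each below 2³¹), so a stage rerun in isolation reproduces its in-chain
behaviour. Every run writes a manifest with the tool version, a config
hash, per-output SHA-256 checksums and stage timings; identical configs
produce identical checksums.

## Problem sizes and numerical choices

The test and acceptance workloads run on one CPU in minutes: 300–600
genes × 300–900 cells for count fixtures, 500 cells × 100 genes for the
reconstruction benchmark, 50 random LP instances of ≤ 20 cells × 10
genes, 100 seeded repeats for rank-sum calibration. Numerical
tie-breaks and tolerances: LP objective agreement is asserted to 1e-6;
per-gene standardisation treats residual standard deviations below
`1e-10 · (max|value| + 1)` as zero (a perfectly fit gene yields a zero
row rather than amplified rounding noise); min-max scaling maps
constant genes to 0; score and trajectory thresholds are strict
inequalities; cluster labels are compacted to 0..k−1 in order of first
appearance with DBSCAN noise kept at −1.

## Known limitations

- The autoencoder is full-batch NumPy; it is sized for desk-scale and
  tutorial datasets (≲ 10⁴ cells × 10⁴ genes), not atlas-scale runs.
- The LP solve is dense; gene sets beyond a few thousand members with
  tens of thousands of training cells will be slow.
- Louvain determinism is enforced by seeding the graph library's RNG;
  partitions may differ across igraph versions.
- The sparsity penalty's weight β and target ρ interact with data scale;
  the defaults are starting points, not calibrated values.
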