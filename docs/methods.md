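# Methods

## Problem and overall design

`mscontab` clusters *cancer cohorts* — entire cancer types, not individual
patients — from their somatic coding single-nucleotide substitution
profiles. Each cohort is summarized by two complementary tabular views:

* **Gene view** `x_g ∈ R^300`: for the cohort's 25 most frequently mutated
  protein-coding genes, the counts of the 12 ordered substitution
  categories (A>C, A>G, …, T>G in fixed lexicographic order), flattened
  row-major in rank order. Cohorts with fewer than 25 mutated genes are
  zero-padded so the encoder input width is constant.
* **Chromosome view** `x_c ∈ R^288`: the same 12 categories tallied per
  canonical chromosome (1–22, X, Y) and divided by chromosome length in bp
  (GRCh38 primary-assembly lengths by default, overridable via a TSV).

The 12 categories are strand-specific on purpose: complementary pairs such
as C>T and G>A genuinely differ in observed load, so collapsing to the
6 pyrimidine classes would discard signal.

Two encoders — one per view — map the scaled vectors to 64-dimensional
latents, a 2-layer projection head maps each latent into the contrastive
space, and the normalized temperature-scaled cross-entropy (NT-Xent) loss
pulls the two projections of the same cohort together while pushing apart
projections of different cohorts in the same mini-batch. After training,
the two view projections are fused (default: average of the L2-normalized
views, re-normalized, keeping 64 dims; concatenation to 128 dims is
available) and k-means (k = 2, 10 k-means++ restarts) partitions the
cohorts. Internal validity is scored with Silhouette, Davies–Bouldin and
Calinski–Harabasz indices, in the original embedding space and, separately
tagged, in a 2-D UMAP/t-SNE projection — the two spaces give very
different absolute values and are never mixed.

## Filtering

Input rows are parsed without silent drops, then filtered in a fixed rule
order — malformed → bad_chromosome → not_snv → ref_equals_alt →
alt_transcript → non_coding — with each record charged to the first rule
it violates, so reports are deterministic and conserve counts exactly.
Structural validity precedes semantic rules. The alternative-transcript
rule drops any gene symbol *containing* `_ENST` (slightly broader than a
suffix match, defensively; the marker is configurable). When the input has
no coding-status column all rows are assumed coding, since COSMIC-style
extracts are typically pre-restricted to coding variants. Mitochondrial
and alt-contig records fall under `bad_chromosome` because the 24-label
chromosome view has no row for them. Duplicate (sample, variant) rows are
kept by default; `dedup_records` / `--dedup` collapses them.

By default the chromosome view counts **all** retained coding SNVs of the
cohort; `restrict_to_top_genes` limits it to the cohort's top-25 genes.
The restricted variant makes the two views share a gene population, the
default keeps the chromosome view genuinely genome-wide; both are exposed
because either reading of the two-view design is defensible.

## Input scaling

Counts and rates are log1p-transformed (chromosome rates are first
expressed per Mb so both views occupy comparable numeric ranges), then
standardized with the **view-global** mean and standard deviation
(`log1p_global`, the default). A per-feature z-score variant
(`log1p_zscore`, constant features mapped to 0) is provided but not
default, for a reason worth recording: per-feature whitening equalizes the
variance of informative features and pure sampling noise. Under the
instance-discrimination pressure of NT-Xent the encoders then learn to
tell *individual cohorts* apart from whitened noise directions and spread
all cohorts uniformly on the sphere, washing out group structure — on
synthetic data with planted clusters, recovery collapses from ARI 1.0 to
ARI ≈ 0 even though k-means on the raw features separates the clusters
perfectly. The global affine keeps relative feature variances, so the
burden and spectrum amplitudes that distinguish groups of cancers dominate
the representation, which is also the regime implied by strongly coherent
within-group cosine similarities in real cohort data.

## Encoder

The encoder is a sequential-attention tabular network. Hyperparameters
(all in `EncoderParams`): 3 decision steps, decision and attention widths
n_d = n_a = 64, relaxation γ = 1.3, feature transformers with 2 shared +
2 step-specific GLU blocks (width n_d + n_a, residuals scaled by √0.5).
At each step an attentive transformer maps the previous step's attention
features through a linear layer, multiplies by the running prior and
applies **sparsemax** — the Euclidean projection onto the probability
simplex, computed by the sorted-threshold algorithm — giving a sparse
mask with exact zeros; the prior is updated by `prior *= (γ − mask)` so
features used early are discounted later. Masked features pass through
the feature transformer; the ReLU'd decision half of its output is summed
across steps into the 64-dim latent, and the attention half feeds the next
step. Per-step masks are aggregated into feature importances by weighting
each step's mask with its total decision output and normalizing per
sample.

Normalization inside blocks is a trainable per-feature affine map
(identity at init) rather than batch normalization: with mini-batches of
8 cohorts and a few dozen cohorts total, batch statistics are noisy and
make evaluation depend on batch composition, whereas the affine variant is
deterministic and stable. Standard batch normalization remains available
(`normalization="batch"`).

The whole model runs on a small reverse-mode autodiff core
(`mscontab.autodiff`) over float64 NumPy arrays: broadcasting arithmetic,
matmul, GLU nonlinearities, reductions, slicing/concatenation, a custom
sparsemax backward (support-restricted centering of the upstream
gradient), and Adam. Gradient correctness is checked against central
finite differences in the test suite; float64 on a single CPU thread keeps
full training runs bit-reproducible for a fixed seed.

## Contrastive objective

For a mini-batch of N cohorts the 2N projections are L2-normalized and
each anchor i with partner j incurs

    L_i = −log [ exp(s_ij/τ) / Σ_{k≠i} exp(s_ik/τ) ],   τ = 0.5,

with cosine similarity s; the batch loss averages the 2N anchors in both
view directions. The denominator excludes the *anchor* (the standard
SimCLR convention). A variant that instead excludes the positive is
available (`denominator="positive"`) but is not the default: keeping the
anchor's self-similarity exp(1/τ) in its own denominator mostly rewards
shrinking a constant, which is not a useful alignment signal.

Training protocol: 100 epochs of Adam (lr 1e-3), mini-batches of 8 drawn
by epoch-level shuffling without replacement (a trailing batch with fewer
than two cohorts is merged into the previous batch — NT-Xent needs at
least one in-batch negative), temperature 0.5, single seed (default 42)
driving weight init, shuffling and the optimizer. Fewer than 3 cohorts is
an error; a non-finite loss aborts with a diagnostic rather than training
on.

## Synthetic data

The generator emits a COSMIC-shaped flat SNV table with planted cohort
clusters. Defaults: 40 cohorts, 2 equally sized clusters, a 500-gene
vocabulary with power-law propensities whose top-25 slots share a 60 %
backbone across clusters plus cluster-specific driver genes; cluster 0 is
transition-heavy (C>T weight 8, G>A weight 6, flat elsewhere) with mean
burden 3000 and chromosome load concentrated on chromosomes 19/7/9/1;
cluster 1 is flatter with elevated G>T (weight 3), mean burden 1200 and
length-proportional chromosome load. Burden and spectra are independent
knobs so tests can isolate either signal. Within-cluster variation:
per-cohort Dirichlet perturbation of the substitution bias (concentration
150) and of the gene propensities (concentration 5000), Poisson burden,
and multinomial sampling noise; mutations are distributed over 50 samples
per cohort. A `separation_dial(cfg, level)` interpolates every cluster
profile toward the across-cluster mean: level 0 is a true null (identical
clusters), level 1 the configured separation.

What the generator does *not* emulate: trinucleotide context, selection,
hypermutator samples, clonal structure, inter-gene length differences, or
correlated gene–chromosome placement (genes are not tied to chromosomes).
Passing recovery tests therefore show that the pipeline extracts planted
burden/spectrum/propensity structure — not that it would reproduce any
particular real-data clustering.

## Baselines and ablations

All comparison methods consume the concatenated 588-dim feature vector
and are scored by the *same* k-means + validity-metric code path: NMF
factor scores on the raw non-negative features (default rank 8; rank = n
is accepted but degenerate), Ward-linkage agglomerative labels (metrics
on the feature matrix itself), a shallow autoencoder's 64-dim bottleneck,
a SimCLR-style single-MLP encoder trained with NT-Xent on feature-dropout
(p = 0.1) + Gaussian-jitter (σ = 0.1) augmentations, and DeepCluster-style
alternation of k-means pseudo-labels (4 by default) and classifier
updates, with a fresh classifier head per round and a collapse guard that
stops re-clustering once the representation degenerates.

Ablations replace the gene-view encoder, the chromosome-view encoder, or
both with a 2-layer MLP of matched output width, or keep both encoders
but swap NT-Xent for a non-contrastive alignment objective (mean squared
distance between the normalized paired projections). The non-contrastive
variant deliberately lacks any repulsive term; its tendency to collapse is
part of what the ablation measures.

## Numerical choices and edge cases

* Gene ranking ties break alphabetically; prototype and neighbor ties
  likewise (after rounding similarities to 12 decimals to avoid
  float-order artifacts).
* Silhouette terms of singleton clusters are 0; Davies–Bouldin with
  coincident centroids reports ∞ for that pair; Calinski–Harabasz with
  zero within-cluster variance reports ∞ with a warning.
* Validity metrics use Euclidean distance on the fused embeddings (the
  similarity analyses — heatmap, prototypes, neighbors — use cosine).
* Sparsemax rejects empty or non-finite input; its backward pass restricts
  the gradient to the support set.
* UMAP runs with `n_neighbors = min(15, n−1)` and a fixed `random_state`;
  t-SNE with perplexity `max(2, min(30, (n−1)/3))`, PCA init, fixed seed.
  Both are treated as external deterministic 2-D projection contracts.

## Problem sizes used in the checks

The automated checks run the full protocol (100 epochs, batch 8) on the
generator defaults: 40 cohorts, ~84 k mutations per dataset, five
data/training seeds for the recovery, null-calibration, ablation-ordering
and projection comparisons, 200 random batches for the loss oracle, 1000
random vectors for the sparsemax oracle. One full training takes on the
order of ten seconds of CPU.

## Known limitations

* The NT-Xent objective is an instance discriminator: with long training
  or whitened inputs it will eventually spread cohorts uniformly and
  dissolve group structure (see *Input scaling*). The latent-space fusion
  of `h_g`/`h_c` retains cluster structure longer than the projection
  fusion; both are exposed.
* With ~40 cohorts, validity indices have high variance; comparisons
  across methods are made on medians over seeds.
* The checkpoint format stores raw parameter arrays plus a JSON config; it
  is not portable across architecture changes.
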