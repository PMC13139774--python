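# mscontab

Cohort-level cancer clustering from somatic mutation signatures with
multi-scale contrastive learning.

Most unsupervised cancer genomics operates at the patient level. This
package addresses the complementary question: which *entire cancer types*
share mutational machinery? It takes a flat table of somatic coding
single-nucleotide variants (COSMIC-mutant-export style: one row per
cohort / sample / gene / chromosome / position / ref / alt), summarizes
each cohort at two scales, aligns the scales with contrastive learning,
and clusters the resulting cohort embeddings. It is aimed at cancer
genomicists who want a reproducible, inspectable pipeline from a mutation
table to validated cohort clusters, plus the synthetic benchmark needed to
test such a pipeline offline.

## Method

For each cohort two signature views are built:

* **gene view** `x_g ∈ R^300` — counts of the 12 ordered nucleotide
  substitutions (A>C … T>G, strand-specific) for the cohort's 25 most
  frequently mutated genes, flattened in rank order;
* **chromosome view** `x_c ∈ R^288` — the same 12 categories per
  chromosome (1–22, X, Y), divided by chromosome length.

Two sequential-attention tabular encoders (sparsemax feature-selection
masks over 3 decision steps, GLU feature transformers) map the views to
64-dim latents `h_g, h_c`; 2-layer projection heads give `z_g, z_c`. The
NT-Xent objective treats a cohort's two views as a positive pair against
in-batch negatives:

    L_i = −log [ exp(s(z_i, z_j)/τ) / Σ_{k≠i} exp(s(z_i, z_k)/τ) ],  τ = 0.5

with cosine similarity `s`; the batch loss averages all 2N anchors.
Training: 100 epochs, Adam (lr 1e-3), batch size 8, fixed seed. The
normalized view projections are averaged and re-normalized into one
64-dim embedding per cohort, partitioned by k-means (k = 2) and scored
with Silhouette / Davies–Bouldin / Calinski–Harabasz indices, in the
original space and in a seeded 2-D t-SNE/UMAP projection. Downstream
analyses include cosine-similarity heatmap ordering, cluster prototypes,
3-nearest-neighbor tables, per-cluster substitution spectra and
chromosome loads, and top-gene set overlaps. Five baseline embeddings
(NMF, Ward, autoencoder, SimCLR-MLP, DeepCluster) and four ablations
(MLP instead of either/both encoders; alignment loss instead of NT-Xent)
run through the identical clustering pipeline.

The deep-learning components run on a small float64 NumPy autodiff core
(`mscontab.autodiff`), which keeps every training run bit-reproducible on
CPU for a fixed seed.

A synthetic-cohort generator (`mscontab.synth`) emits COSMIC-shaped
mutation tables with planted cluster structure — cluster-specific
substitution biases, burdens, chromosome profiles and driver-gene sets,
with a dial that interpolates the clusters down to an exact null — so the
whole pipeline is testable end to end without licensed data.

## Worked example

```python
from mscontab import (SynthConfig, generate_dataset, filter_records,
                      build_feature_views, train_ms_contab, TrainConfig,
                      kmeans_cluster, internal_metrics)
from mscontab.cluster import within_between_similarity
from sklearn.metrics import adjusted_rand_score

dataset = generate_dataset(SynthConfig(n_cohorts=40, seed=1))
records, report = filter_records(dataset.records)
views = build_feature_views(records)
model, emb = train_ms_contab(views, cfg=TrainConfig(epochs=100, seed=42))
result = kmeans_cluster(emb.Z_fused, k=2, seed=42, cohorts=emb.cohorts)
metrics = internal_metrics(emb.Z_fused, result.labels)
```

Output of the full script (see the printed lines below each step):

```
83329 retained SNVs across 40 cohorts
gene view (40, 300), chromosome view (40, 288)
NT-Xent mean loss: epoch 1 = 3.095, epoch 100 = 1.696
silhouette = 0.673, Davies-Bouldin = 0.592, Calinski-Harabasz = 58.6
mean cosine similarity: {'within_0': 0.996, 'within_1': 0.225, 'between': -0.511}
ARI vs planted labels = 1.000
```

Reading this: the contrastive loss drops as the two views align; the
fused embeddings separate into two clusters that are internally coherent
(positive within-cluster mean cosine similarity) and mutually repelled
(negative between-cluster similarity); and the recovered partition matches
the generator's planted labels exactly (adjusted Rand index 1.0).

The same pipeline runs from the shell:

```bash
ms-contab synth --out data/ --n-cohorts 40 --seed 1
ms-contab run-all --out results/            # filter → featurize → train → cluster → evaluate
ms-contab baselines --input data/mutations.tsv --method nmf
ms-contab ablate --input data/mutations.tsv --mode no_contrastive
```

`run-all` writes every artifact (filtered table, both views, embeddings,
loss history, cluster labels, metrics for both spaces, similarity matrix,
neighbor table, spectra, gene overlaps) with a checksummed manifest, and
deterministic stages reproduce byte-identical files on rerun.

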