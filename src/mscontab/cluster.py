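"""Clustering of cohort embeddings and all downstream analyses.

k-means partitions the fused embeddings; internal validity is scored with
Silhouette, Davies-Bouldin and Calinski-Harabasz indices (Euclidean, on
either the original embedding space or a 2-D projection, never silently
mixed — the ``space_tag`` records which).  The same module derives the
descriptive outputs: cosine-similarity matrix ordered by cluster, cluster
prototypes, 3-nearest-neighbor tables, per-cluster substitution spectra and
chromosome loads, and top-gene set overlaps.

The validity indices are implemented from their definitions here and
cross-checked against scikit-learn in the test suite; a singleton cluster
contributes a silhouette term of 0 for its point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .signatures import (
    CANONICAL_CHROMOSOMES,
    SUBSTITUTIONS,
    ChromosomeSignature,
    GeneSignature,
)

__all__ = [
    "ClusterResult", "MetricBundle", "kmeans_cluster", "internal_metrics",
    "cosine_matrix", "cluster_prototypes", "nearest_neighbors",
    "cluster_spectra", "gene_set_overlap", "project_2d",
]


@dataclass
class ClusterResult:
    cohorts: list[str]
    labels: np.ndarray
    k: int
    centroids: np.ndarray
    seed: int

    def members(self, cluster: int) -> list[str]:
        return [c for c, l in zip(self.cohorts, self.labels) if l == cluster]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cohort": self.cohorts, "cluster": self.labels})


@dataclass
class MetricBundle:
    silhouette: float
    davies_bouldin: float
    calinski_harabasz: float
    space_tag: str = "original"

    def as_dict(self) -> dict:
        return {
            "silhouette": self.silhouette,
            "davies_bouldin": self.davies_bouldin,
            "calinski_harabasz": self.calinski_harabasz,
            "space_tag": self.space_tag,
        }


def kmeans_cluster(
    Z: np.ndarray,
    k: int = 2,
    seed: int = 42,
    n_init: int = 10,
    cohorts: list[str] | None = None,
) -> ClusterResult:
    """Best of ``n_init`` k-means++ restarts by within-cluster sum of squares."""
    Z = np.atleast_2d(np.asarray(Z, float))
    n = Z.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(Z)
    if cohorts is None:
        cohorts = [f"cohort_{i}" for i in range(n)]
    return ClusterResult(cohorts=list(cohorts), labels=km.labels_.astype(int),
                         k=k, centroids=km.cluster_centers_, seed=seed)


def internal_metrics(Z: np.ndarray, labels: np.ndarray,
                     space_tag: str = "original") -> MetricBundle:
    """Silhouette, Davies-Bouldin and Calinski-Harabasz (Euclidean).

    silhouette(point) = (b - a)/max(a, b) with a = mean intra-cluster
    distance and b = smallest mean distance to another cluster (0 for
    singleton clusters); DBI = mean over clusters of the worst pairwise
    (S_i + S_j)/M_ij with S the mean distance to the centroid and M the
    centroid distance; CH = [BSS/(k-1)] / [WSS/(n-k)].
    """
    Z = np.atleast_2d(np.asarray(Z, float))
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    k, n = len(uniq), Z.shape[0]
    if k < 2:
        raise ValueError("need at least 2 clusters for internal metrics")
    D = cdist(Z, Z)

    # silhouette
    sil_terms = np.zeros(n)
    for idx in range(n):
        own = labels == labels[idx]
        n_own = own.sum()
        if n_own == 1:
            continue  # singleton: term stays 0
        a = D[idx, own].sum() / (n_own - 1)
        b = min(D[idx, labels == c].mean() for c in uniq if c != labels[idx])
        sil_terms[idx] = (b - a) / max(a, b)
    silhouette = float(sil_terms.mean())

    # scatter per cluster + centroids
    cents = np.stack([Z[labels == c].mean(axis=0) for c in uniq])
    S = np.array([
        np.linalg.norm(Z[labels == c] - cents[i], axis=1).mean()
        for i, c in enumerate(uniq)
    ])
    M = cdist(cents, cents)
    ratios = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            if i != j:
                ratios[i, j] = (S[i] + S[j]) / M[i, j] if M[i, j] > 0 else np.inf
    dbi = float(np.mean([ratios[i].max() for i in range(k)]))

    mean_all = Z.mean(axis=0)
    counts = np.array([(labels == c).sum() for c in uniq])
    bss = float((counts * ((cents - mean_all) ** 2).sum(axis=1)).sum())
    wss = float(sum(((Z[labels == c] - cents[i]) ** 2).sum()
                    for i, c in enumerate(uniq)))
    if wss == 0:
        warnings.warn("zero within-cluster variance; CH index is infinite")
        ch = np.inf
    else:
        ch = (bss / (k - 1)) / (wss / (n - k))
    return MetricBundle(silhouette=silhouette, davies_bouldin=dbi,
                        calinski_harabasz=float(ch), space_tag=space_tag)


def _unit_rows(Z: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(Z, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero row in embedding matrix")
    return Z / norms


def cosine_matrix(
    Z: np.ndarray,
    cohorts: list[str] | None = None,
    labels: np.ndarray | None = None,
) -> pd.DataFrame:
    """Pairwise cosine similarity; rows/columns ordered by (cluster, name)."""
    Z = np.atleast_2d(np.asarray(Z, float))
    n = Z.shape[0]
    if cohorts is None:
        cohorts = [f"cohort_{i}" for i in range(n)]
    if labels is None:
        labels = np.zeros(n, dtype=int)
    order = sorted(range(n), key=lambda i: (labels[i], cohorts[i]))
    U = _unit_rows(Z)[order]
    names = [cohorts[i] for i in order]
    return pd.DataFrame(U @ U.T, index=names, columns=names)


def within_between_similarity(Z: np.ndarray, labels: np.ndarray) -> dict:
    """Mean cosine similarity within each cluster and between clusters."""
    U = _unit_rows(np.atleast_2d(np.asarray(Z, float)))
    S = U @ U.T
    labels = np.asarray(labels)
    out: dict[str, float] = {}
    uniq = np.unique(labels)
    for c in uniq:
        m = labels == c
        block = S[np.ix_(m, m)]
        iu = np.triu_indices(block.shape[0], k=1)
        out[f"within_{c}"] = float(block[iu].mean()) if iu[0].size else 1.0
    if len(uniq) >= 2:
        pair_vals = [
            S[np.ix_(labels == a, labels == b)].mean()
            for ai, a in enumerate(uniq) for b in uniq[ai + 1:]
        ]
        out["between"] = float(np.mean(pair_vals))
    return out


def cluster_prototypes(Z: np.ndarray, labels: np.ndarray,
                       cohorts: list[str]) -> dict[int, str]:
    """Per cluster, the member with maximal mean cosine similarity to its
    co-members (ties alphabetical; a singleton is its own prototype)."""
    U = _unit_rows(np.atleast_2d(np.asarray(Z, float)))
    labels = np.asarray(labels)
    protos: dict[int, str] = {}
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if idx.size == 1:
            protos[int(c)] = cohorts[idx[0]]
            continue
        sub = U[idx] @ U[idx].T
        mean_sim = (sub.sum(axis=1) - 1.0) / (idx.size - 1)
        best = min(
            range(idx.size),
            key=lambda i: (-round(mean_sim[i], 12), cohorts[idx[i]]),
        )
        protos[int(c)] = cohorts[idx[best]]
    return protos


def nearest_neighbors(Z: np.ndarray, cohorts: list[str], m: int = 3) -> pd.DataFrame:
    """Top-m most cosine-similar cohorts per cohort (self excluded)."""
    Z = np.atleast_2d(np.asarray(Z, float))
    n = Z.shape[0]
    if n <= m:
        raise ValueError(f"need more than {m} cohorts, got {n}")
    S = _unit_rows(Z) @ _unit_rows(Z).T
    rows = []
    for i in range(n):
        others = [j for j in range(n) if j != i]
        ranked = sorted(others, key=lambda j: (-round(S[i, j], 12), cohorts[j]))[:m]
        row: dict = {"cohort": cohorts[i]}
        for r, j in enumerate(ranked, start=1):
            row[f"neighbor_{r}"] = cohorts[j]
            row[f"score_{r}"] = float(S[i, j])
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class SpectrumProfile:
    """Per-cluster mean substitution spectrum (raw gene-view counts summed
    over genes) and mean length-normalized chromosome load."""

    substitution_means: pd.DataFrame  # clusters x 12
    chromosome_means: pd.DataFrame    # clusters x 24


def cluster_spectra(
    gene_sigs: dict[str, GeneSignature],
    chrom_sigs: dict[str, ChromosomeSignature],
    labels: dict[str, int],
) -> SpectrumProfile:
    """Unweighted per-cluster means of the 12 substitution totals and of
    the 24 normalized chromosome loads; each cohort counts once."""
    missing = [c for c in labels if c not in gene_sigs or c not in chrom_sigs]
    if missing:
        raise ValueError(f"labels without signatures: {missing}")
    clusters = sorted(set(labels.values()))
    sub_rows, chrom_rows = [], []
    for cl in clusters:
        members = [c for c, l in labels.items() if l == cl]
        sub_rows.append(np.mean(
            [gene_sigs[c].matrix.sum(axis=0) for c in members], axis=0))
        chrom_rows.append(np.mean(
            [chrom_sigs[c].matrix.sum(axis=1) for c in members], axis=0))
    return SpectrumProfile(
        substitution_means=pd.DataFrame(
            sub_rows, index=clusters, columns=list(SUBSTITUTIONS)),
        chromosome_means=pd.DataFrame(
            chrom_rows, index=clusters,
            columns=[f"chr{c}" for c in CANONICAL_CHROMOSOMES]),
    )


def gene_set_overlap(set_a: set[str], set_b: set[str]) -> dict:
    """Venn summary of two clusters' mutated-gene sets."""
    if not set_a or not set_b:
        warnings.warn("empty gene set in overlap comparison")
    shared = set_a & set_b
    return {
        "shared": sorted(shared),
        "unique_a": sorted(set_a - shared),
        "unique_b": sorted(set_b - shared),
        "n_shared": len(shared),
        "n_unique_a": len(set_a - shared),
        "n_unique_b": len(set_b - shared),
    }


def cluster_gene_sets(gene_sigs: dict[str, GeneSignature],
                      labels: dict[str, int]) -> dict[int, set[str]]:
    """Union of member cohorts' top-gene lists, per cluster."""
    out: dict[int, set[str]] = {}
    for cohort, cl in labels.items():
        out.setdefault(cl, set()).update(gene_sigs[cohort].genes)
    return out


def project_2d(Z: np.ndarray, method: str = "umap", seed: int = 42) -> np.ndarray:
    """Delegate to an external 2-D projection (deterministic given seed)."""
    Z = np.atleast_2d(np.asarray(Z, float))
    n = Z.shape[0]
    if n < 4:
        raise ValueError("need at least 4 points for a 2-D projection")
    if method == "umap":
        import umap

        nn = min(15, n - 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reducer = umap.UMAP(n_components=2, n_neighbors=nn,
                                random_state=seed, n_jobs=1)
            return np.asarray(reducer.fit_transform(Z), float)
    if method == "tsne":
        from sklearn.manifold import TSNE

        perplexity = max(2.0, min(30.0, (n - 1) / 3.0))
        ts = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
                  init="pca")
        return np.asarray(ts.fit_transform(Z), float)
    raise ValueError(f"unknown projection method {method!r}")
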