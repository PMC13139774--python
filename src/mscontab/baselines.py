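"""Comparison embeddings and ablation variants, all scored through the
same downstream pipeline (k-means + internal validity metrics).

Baselines (over the concatenated gene-level + chromosome-level features,
588 dims):

* ``nmf`` — non-negative matrix factorization factor scores (on the raw,
  non-negative counts/rates);
* ``hierarchical_ward`` — Ward-linkage agglomerative labels, metrics
  computed on the feature matrix itself;
* ``autoencoder`` — bottleneck codes of a shallow reconstruction network;
* ``simclr_mlp`` — a single MLP encoder trained with NT-Xent on
  feature-dropout + jitter augmentations of the concatenated vector;
* ``deepcluster`` — alternating k-means pseudo-labels and classifier
  updates on an MLP encoder.

Ablations swap out pieces of the full dual-encoder model: replacing either
or both TabNet encoders with a plain 2-layer MLP, or keeping both TabNets
but replacing the contrastive objective with a non-contrastive
view-alignment loss (mean squared distance between paired projections).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam, Tensor
from .cluster import MetricBundle, internal_metrics, kmeans_cluster
from .contrastive import (
    EmbeddingSet,
    MsConTabModel,
    ProjectionHead,
    ProjectionHeadParams,
    TrainConfig,
    _make_batches,
    train_dual,
)
from .signatures import FeatureViews
from .tabnet import EncoderParams, Linear, TabNetEncoder

BASELINE_METHODS = ("nmf", "hierarchical_ward", "autoencoder", "simclr_mlp",
                    "deepcluster")
ABLATION_MODES = ("no_gene_tabenc", "no_chrom_tabenc", "no_both_tabenc",
                  "no_contrastive")


@dataclass
class BaselineSpec:
    method: str
    k: int = 2
    seed: int = 42
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.method not in BASELINE_METHODS:
            raise ValueError(f"unknown baseline method {self.method!r}")


@dataclass
class AblationSpec:
    mode: str
    cfg: TrainConfig = field(default_factory=TrainConfig)
    k: int = 2
    mlp_hidden: int = 128

    def __post_init__(self):
        if self.mode not in ABLATION_MODES:
            raise ValueError(f"unknown ablation mode {self.mode!r}")


@dataclass
class MLPEncoderParams:
    input_dim: int
    hidden_dim: int = 128
    n_d: int = 64
    seed: int = 42


class MLPEncoder:
    """Plain 2-layer MLP encoder with the same protocol as the TabNet
    encoder (used by the ablations and the SimCLR/DeepCluster baselines)."""

    def __init__(self, params: MLPEncoderParams):
        self.params = params
        rng = np.random.default_rng(params.seed)
        self.fc1 = Linear(params.input_dim, params.hidden_dim, rng)
        self.fc2 = Linear(params.hidden_dim, params.n_d, rng)

    def encode(self, X, training: bool = True):
        x = X if isinstance(X, Tensor) else Tensor(np.atleast_2d(X))
        return self.fc2(self.fc1(x).relu()), None

    def parameters(self):
        return self.fc1.parameters() + self.fc2.parameters()


def _concat_views(views: FeatureViews, raw: bool = False) -> np.ndarray:
    if raw:
        return np.hstack([views.Xg_raw, views.Xc_raw])
    return np.hstack([views.Xg, views.Xc])


# ---------------------------------------------------------------------------
# individual baselines


def _nmf_embedding(X: np.ndarray, spec: BaselineSpec) -> np.ndarray:
    from sklearn.decomposition import NMF

    if np.any(X < 0):
        raise ValueError("NMF requires non-negative input; use the raw views")
    rank = int(spec.hyperparameters.get("rank", 8))
    rank = min(rank, min(X.shape))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = NMF(n_components=rank, init="nndsvda", random_state=spec.seed,
                    max_iter=5000, tol=1e-10)
        return model.fit_transform(X)


def _ward_labels(X: np.ndarray, spec: BaselineSpec) -> np.ndarray:
    from sklearn.cluster import AgglomerativeClustering

    return AgglomerativeClustering(n_clusters=spec.k, linkage="ward").fit(X).labels_


def _autoencoder_embedding(X: np.ndarray, spec: BaselineSpec) -> np.ndarray:
    hp = spec.hyperparameters
    bottleneck = int(hp.get("bottleneck", 64))
    hidden = int(hp.get("hidden", 128))
    epochs = int(hp.get("epochs", 100))
    lr = float(hp.get("learning_rate", 1e-3))
    batch_size = int(hp.get("batch_size", 8))
    rng = np.random.default_rng(spec.seed)
    d = X.shape[1]
    enc1 = Linear(d, hidden, rng)
    enc2 = Linear(hidden, bottleneck, rng)
    dec1 = Linear(bottleneck, hidden, rng)
    dec2 = Linear(hidden, d, rng)
    params = enc1.parameters() + enc2.parameters() + dec1.parameters() + dec2.parameters()
    opt = Adam(params, lr=lr)
    loop_rng = np.random.default_rng(spec.seed + 1)

    def encode(xs: np.ndarray) -> Tensor:
        return enc2(enc1(Tensor(xs)).relu())

    for _ in range(epochs):
        for idx in _make_batches(X.shape[0], batch_size, loop_rng):
            code = encode(X[idx])
            recon = dec2(dec1(code).relu())
            diff = recon - Tensor(X[idx])
            loss = (diff * diff).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
    return encode(X).data


def _augment(X: np.ndarray, rng: np.random.Generator,
             dropout: float, jitter: float) -> np.ndarray:
    keep = rng.random(X.shape) >= dropout
    return X * keep + rng.normal(0.0, jitter, size=X.shape)


def _simclr_embedding(X: np.ndarray, spec: BaselineSpec) -> np.ndarray:
    from .contrastive import _nt_xent_loss_tensor

    hp = spec.hyperparameters
    epochs = int(hp.get("epochs", 100))
    tau = float(hp.get("temperature", 0.5))
    dropout = float(hp.get("dropout", 0.1))
    jitter = float(hp.get("jitter", 0.1))
    batch_size = int(hp.get("batch_size", 8))
    enc = MLPEncoder(MLPEncoderParams(input_dim=X.shape[1], seed=spec.seed))
    head = ProjectionHead(ProjectionHeadParams(seed=spec.seed + 1))
    opt = Adam(enc.parameters() + head.parameters(),
               lr=float(hp.get("learning_rate", 1e-3)))
    rng = np.random.default_rng(spec.seed + 2)
    for _ in range(epochs):
        for idx in _make_batches(X.shape[0], batch_size, rng):
            Z1, _ = enc.encode(_augment(X[idx], rng, dropout, jitter))
            Z2, _ = enc.encode(_augment(X[idx], rng, dropout, jitter))
            loss = _nt_xent_loss_tensor(head(Z1), head(Z2), tau)
            opt.zero_grad()
            loss.backward()
            opt.step()
    Z, _ = enc.encode(X, training=False)
    return Z.data


def _softmax_ce(logits: Tensor, labels: np.ndarray) -> Tensor:
    n, k = logits.data.shape
    pick = np.zeros((n, k))
    pick[np.arange(n), labels] = 1.0
    return (logits.logsumexp_rows() - (logits * Tensor(pick)).sum(
        axis=1, keepdims=True)).mean()


def _deepcluster_embedding(X: np.ndarray, spec: BaselineSpec) -> np.ndarray:
    hp = spec.hyperparameters
    rounds = int(hp.get("rounds", 20))
    inner_epochs = int(hp.get("inner_epochs", 5))
    n_pseudo = int(hp.get("n_pseudo", 4))
    batch_size = int(hp.get("batch_size", 8))
    enc = MLPEncoder(MLPEncoderParams(input_dim=X.shape[1], seed=spec.seed))
    lr = float(hp.get("learning_rate", 1e-3))
    rng = np.random.default_rng(spec.seed + 2)
    last_good = None
    for r in range(rounds):
        Z, _ = enc.encode(X, training=False)
        # collapse guard: stop re-clustering once the representation has
        # degenerated to (near-)identical points
        k_eff = min(n_pseudo, np.unique(np.round(Z.data, 9), axis=0).shape[0])
        if np.ptp(Z.data, axis=0).max() < 1e-9 or k_eff < 2:
            break
        last_good = Z.data
        pseudo = kmeans_cluster(Z.data, k=k_eff, seed=spec.seed + r).labels
        # fresh classifier head each round (prevents trivial persistence
        # of the previous assignment)
        clf = Linear(enc.params.n_d, k_eff,
                     np.random.default_rng(spec.seed + 100 + r))
        opt = Adam(enc.parameters() + clf.parameters(), lr=lr)
        for _ in range(inner_epochs):
            for idx in _make_batches(X.shape[0], batch_size, rng):
                H, _ = enc.encode(X[idx])
                loss = _softmax_ce(clf(H), pseudo[idx])
                opt.zero_grad()
                loss.backward()
                opt.step()
    Z, _ = enc.encode(X, training=False)
    if np.ptp(Z.data, axis=0).max() < 1e-9 and last_good is not None:
        return last_good
    return Z.data


def run_baseline(
    spec: BaselineSpec, views: FeatureViews,
) -> tuple[np.ndarray, MetricBundle]:
    """Compute a baseline embedding (or labels for Ward) and score it with
    the shared k-means + internal-metrics pipeline."""
    if spec.method == "nmf":
        Z = _nmf_embedding(_concat_views(views, raw=True), spec)
    elif spec.method == "hierarchical_ward":
        X = _concat_views(views)
        labels = _ward_labels(X, spec)
        return labels, internal_metrics(X, labels)
    elif spec.method == "autoencoder":
        Z = _autoencoder_embedding(_concat_views(views), spec)
    elif spec.method == "simclr_mlp":
        Z = _simclr_embedding(_concat_views(views), spec)
    elif spec.method == "deepcluster":
        Z = _deepcluster_embedding(_concat_views(views), spec)
    else:  # pragma: no cover - guarded in BaselineSpec
        raise ValueError(spec.method)
    result = kmeans_cluster(Z, k=spec.k, seed=spec.seed, cohorts=views.cohorts)
    return Z, internal_metrics(Z, result.labels)


# ---------------------------------------------------------------------------
# ablations


def _build_ablation_model(spec: AblationSpec, views: FeatureViews):
    cfg = spec.cfg
    dg, dc = views.Xg.shape[1], views.Xc.shape[1]
    use_mlp_g = spec.mode in {"no_gene_tabenc", "no_both_tabenc"}
    use_mlp_c = spec.mode in {"no_chrom_tabenc", "no_both_tabenc"}
    enc_g = (MLPEncoder(MLPEncoderParams(dg, spec.mlp_hidden, seed=cfg.seed))
             if use_mlp_g else TabNetEncoder(EncoderParams(dg, seed=cfg.seed)))
    enc_c = (MLPEncoder(MLPEncoderParams(dc, spec.mlp_hidden, seed=cfg.seed + 1))
             if use_mlp_c else TabNetEncoder(EncoderParams(dc, seed=cfg.seed + 1)))
    head_g = ProjectionHead(ProjectionHeadParams(seed=cfg.seed + 2))
    head_c = ProjectionHead(ProjectionHeadParams(seed=cfg.seed + 3))
    return enc_g, enc_c, head_g, head_c


def run_ablation(
    spec: AblationSpec, views: FeatureViews,
) -> tuple[EmbeddingSet, MetricBundle]:
    """Train an ablated variant end-to-end and score its fused embedding
    through the identical downstream pipeline."""
    enc_g, enc_c, head_g, head_c = _build_ablation_model(spec, views)
    objective = "mse" if spec.mode == "no_contrastive" else "ntxent"
    _, emb = train_dual(views, enc_g, enc_c, head_g, head_c, spec.cfg,
                        objective=objective)
    result = kmeans_cluster(emb.Z_fused, k=spec.k, seed=spec.cfg.seed,
                            cohorts=views.cohorts)
    return emb, internal_metrics(emb.Z_fused, result.labels)
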