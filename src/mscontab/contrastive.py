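"""Two-view NT-Xent contrastive training of the dual encoders.

Each cohort contributes a positive pair: its gene-level and chromosome-level
projections.  Within a mini-batch of N cohorts the 2N projections are
L2-normalized and every anchor is pulled toward its partner view and pushed
from the 2N-2 other projections via the temperature-scaled cross-entropy

    L_i = -log[ exp(s(z_i, z_j)/tau) / sum_{k != i} exp(s(z_i, z_k)/tau) ]

with cosine similarity s and the anchor excluded from its own denominator
(the standard SimCLR convention; a variant that instead excludes the
positive is available via ``denominator='positive'`` for exactness
studies, but letting the anchor's self-similarity exp(1/tau) dominate its
own denominator is not a useful training signal).  The batch loss averages
the 2N anchor losses, both view directions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .autodiff import Adam, Tensor
from .signatures import FeatureViews
from .tabnet import AttentionMaskTrace, EncoderParams, Linear, TabNetEncoder

__all__ = [
    "TrainConfig", "ProjectionHeadParams", "ProjectionHead", "EmbeddingSet",
    "cosine_similarity", "nt_xent_anchor_loss", "nt_xent_batch_loss",
    "fuse_embeddings", "train_ms_contab", "MsConTabModel",
]


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for zero vectors")
    return float(a @ b / (na * nb))


def _similarity_matrix(Z: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(Z, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero row in embedding matrix")
    U = Z / norms
    return U @ U.T


def nt_xent_anchor_loss(
    i: int,
    batch: np.ndarray,
    tau: float = 0.5,
    pos: int | None = None,
    denominator: str = "anchor",
) -> float:
    """Loss of one anchor in a stacked (2N, d) batch of projections.

    Rows 0..N-1 are one view and N..2N-1 the other; by default row ``i``
    pairs with row ``(i + N) mod 2N``.  ``denominator`` selects which index
    is excluded from the softmax normalizer: the anchor itself ("anchor",
    standard) or the positive ("positive").
    """
    if tau <= 0:
        raise ValueError("temperature must be positive")
    batch = np.asarray(batch, float)
    two_n = batch.shape[0]
    if two_n % 2:
        raise ValueError("batch must stack an even number of projections")
    if pos is None:
        pos = (i + two_n // 2) % two_n
    S = _similarity_matrix(batch)
    logits = S[i] / tau
    excluded = i if denominator == "anchor" else pos
    keep = np.arange(two_n) != excluded
    # stable log-softmax
    m = logits[keep].max()
    log_denom = m + np.log(np.exp(logits[keep] - m).sum())
    return float(log_denom - logits[pos])


def nt_xent_batch_loss(
    Zg: np.ndarray,
    Zc: np.ndarray,
    tau: float = 0.5,
    denominator: str = "anchor",
) -> float:
    """Mean of the 2N anchor losses over both view directions."""
    Zg = np.atleast_2d(np.asarray(Zg, float))
    Zc = np.atleast_2d(np.asarray(Zc, float))
    if Zg.shape != Zc.shape:
        raise ValueError(f"view shape mismatch: {Zg.shape} vs {Zc.shape}")
    batch = np.vstack([Zg, Zc])
    return float(np.mean([
        nt_xent_anchor_loss(i, batch, tau, denominator=denominator)
        for i in range(batch.shape[0])
    ]))


def _nt_xent_loss_tensor(Zg: Tensor, Zc: Tensor, tau: float,
                         denominator: str = "anchor") -> Tensor:
    """Differentiable batch NT-Xent used in the training loop (the NumPy
    scorer above is its independent cross-check in the tests)."""
    n = Zg.data.shape[0]
    Z = Tensor.concat([Zg, Zc], axis=0).l2_normalize_rows()
    St = _matmul_self_transpose(Z) * (1.0 / tau)
    two_n = 2 * n
    pos = (np.arange(two_n) + n) % two_n
    excluded = np.arange(two_n) if denominator == "anchor" else pos
    mask = np.zeros((two_n, two_n))
    mask[np.arange(two_n), excluded] = -1e9
    logits = St + Tensor(mask)
    log_denom = logits.logsumexp_rows()                   # (2n, 1)
    pos_pick = np.zeros((two_n, two_n))
    pos_pick[np.arange(two_n), pos] = 1.0
    pos_logit = (St * Tensor(pos_pick)).sum(axis=1, keepdims=True)
    return (log_denom - pos_logit).mean()


def _matmul_self_transpose(Z: Tensor) -> Tensor:
    """S = Z @ Z.T with gradients flowing into both factors."""

    def backward(g, a=Z):
        if a.requires_grad:
            a._accum(g @ a.data + g.T @ a.data)

    return Tensor._node(Z.data @ Z.data.T, (Z,), backward)


# ---------------------------------------------------------------------------
# model components


@dataclass
class ProjectionHeadParams:
    in_dim: int = 64
    hidden_dim: int = 64
    out_dim: int = 64
    seed: int = 42


class ProjectionHead:
    """2-layer MLP (ReLU) mapping a latent vector into contrastive space."""

    def __init__(self, params: ProjectionHeadParams):
        self.params = params
        rng = np.random.default_rng(params.seed)
        self.fc1 = Linear(params.in_dim, params.hidden_dim, rng)
        self.fc2 = Linear(params.hidden_dim, params.out_dim, rng)

    def __call__(self, h: Tensor) -> Tensor:
        return self.fc2(self.fc1(h).relu())

    def parameters(self):
        return self.fc1.parameters() + self.fc2.parameters()


@dataclass
class TrainConfig:
    """Training protocol: 100 epochs of Adam (lr 1e-3) with mini-batches of
    8 cohorts, NT-Xent temperature 0.5, one fixed seed for everything."""

    epochs: int = 100
    learning_rate: float = 1e-3
    batch_size: int = 8
    temperature: float = 0.5
    seed: int = 42
    fusion_mode: str = "mean"   # "mean" (64-d, unit rows) or "concat" (128-d)
    denominator: str = "anchor"

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (need in-batch negatives)")
        if self.fusion_mode not in {"mean", "concat"}:
            raise ValueError(f"unknown fusion_mode {self.fusion_mode!r}")


@dataclass
class EmbeddingSet:
    """Per-cohort embeddings after training: view latents (h), projections
    (Z) and the fused vector used for clustering."""

    cohorts: list[str]
    Hg: np.ndarray
    Hc: np.ndarray
    Zg: np.ndarray
    Zc: np.ndarray
    Z_fused: np.ndarray
    loss_history: list[float] = field(default_factory=list)

    def to_csv(self, path: str | Path) -> None:
        d = self.Z_fused.shape[1]
        pd.DataFrame(self.Z_fused, index=self.cohorts,
                     columns=[f"z{i}" for i in range(d)]).to_csv(path)


def fuse_embeddings(Zg: np.ndarray, Zc: np.ndarray, mode: str = "mean") -> np.ndarray:
    """Combine the two view projections into one vector per cohort.

    "mean": L2-normalize each view, average, re-normalize (keeps 64 dims);
    "concat": stack to 128 dims.
    """
    Zg = np.atleast_2d(Zg)
    Zc = np.atleast_2d(Zc)
    if Zg.shape[0] != Zc.shape[0]:
        raise ValueError("row mismatch between views")
    if mode == "mean":
        Ug = Zg / np.linalg.norm(Zg, axis=1, keepdims=True)
        Uc = Zc / np.linalg.norm(Zc, axis=1, keepdims=True)
        M = (Ug + Uc) / 2.0
        return M / np.linalg.norm(M, axis=1, keepdims=True)
    if mode == "concat":
        return np.hstack([Zg, Zc])
    raise ValueError(f"unknown fusion mode {mode!r}")


class MsConTabModel:
    """Dual TabNet encoders + projection heads trained contrastively."""

    def __init__(self, enc_g: TabNetEncoder, enc_c: TabNetEncoder,
                 head_g: ProjectionHead, head_c: ProjectionHead, cfg: TrainConfig):
        self.enc_g, self.enc_c = enc_g, enc_c
        self.head_g, self.head_c = head_g, head_c
        self.cfg = cfg

    def parameters(self):
        return (self.enc_g.parameters() + self.enc_c.parameters()
                + self.head_g.parameters() + self.head_c.parameters())

    def embed(self, views: FeatureViews) -> EmbeddingSet:
        """Evaluation-mode pass over all cohorts."""
        Hg, tg = self.enc_g.encode(views.Xg, training=False)
        Hc, tc = self.enc_c.encode(views.Xc, training=False)
        Zg = self.head_g(Hg).data
        Zc = self.head_c(Hc).data
        fused = fuse_embeddings(Zg, Zc, self.cfg.fusion_mode)
        return EmbeddingSet(cohorts=list(views.cohorts), Hg=Hg.data, Hc=Hc.data,
                            Zg=Zg, Zc=Zc, Z_fused=fused)

    def mask_traces(self, views: FeatureViews) -> tuple[AttentionMaskTrace, AttentionMaskTrace]:
        _, tg = self.enc_g.encode(views.Xg, training=False)
        _, tc = self.enc_c.encode(views.Xc, training=False)
        return tg, tc

    # -- persistence ---------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        np.savez(path.with_suffix(".npz"), **arrays)
        meta = {
            "cfg": asdict(self.cfg),
            "enc_g": asdict(self.enc_g.params),
            "enc_c": asdict(self.enc_c.params),
            "head_g": asdict(self.head_g.params),
            "head_c": asdict(self.head_c.params),
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "MsConTabModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        model = cls(
            TabNetEncoder(EncoderParams(**meta["enc_g"])),
            TabNetEncoder(EncoderParams(**meta["enc_c"])),
            ProjectionHead(ProjectionHeadParams(**meta["head_g"])),
            ProjectionHead(ProjectionHeadParams(**meta["head_c"])),
            TrainConfig(**meta["cfg"]),
        )
        with np.load(path.with_suffix(".npz")) as data:
            for i, p in enumerate(model.parameters()):
                p.data[...] = data[f"p{i}"]
        return model


def _make_batches(n: int, batch_size: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Epoch-level shuffle without replacement; a trailing batch with fewer
    than 2 cohorts is merged into the previous one."""
    order = rng.permutation(n)
    batches = [order[i:i + batch_size] for i in range(0, n, batch_size)]
    if len(batches) > 1 and len(batches[-1]) < 2:
        batches[-2] = np.concatenate([batches[-2], batches[-1]])
        batches.pop()
    return batches


def train_dual(
    views: FeatureViews,
    enc_g,
    enc_c,
    head_g: ProjectionHead,
    head_c: ProjectionHead,
    cfg: TrainConfig,
    objective: str = "ntxent",
) -> tuple[MsConTabModel, EmbeddingSet]:
    """Train an arbitrary dual-encoder pair on the two feature views.

    ``objective`` is "ntxent" (contrastive) or "mse" (non-contrastive
    view alignment: mean squared distance between the paired projections —
    used by the ablation study).  Encoders only need the
    ``encode(X, training) -> (Tensor, trace)`` / ``parameters()`` protocol,
    which both the TabNet encoder and the plain MLP replacement satisfy.
    Fully reproducible given ``cfg.seed``.
    """
    if objective not in {"ntxent", "mse"}:
        raise ValueError(f"unknown objective {objective!r}")
    n = views.n_cohorts
    if n < 3:
        raise ValueError(f"need at least 3 cohorts, got {n}")
    model = MsConTabModel(enc_g, enc_c, head_g, head_c, cfg)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    history: list[float] = []
    for epoch in range(cfg.epochs):
        losses = []
        for idx in _make_batches(n, cfg.batch_size, rng):
            Hg, _ = model.enc_g.encode(views.Xg[idx], training=True)
            Hc, _ = model.enc_c.encode(views.Xc[idx], training=True)
            Zg, Zc = model.head_g(Hg), model.head_c(Hc)
            if objective == "ntxent":
                loss = _nt_xent_loss_tensor(Zg, Zc, cfg.temperature,
                                            cfg.denominator)
            else:
                diff = Zg.l2_normalize_rows() - Zc.l2_normalize_rows()
                loss = (diff * diff).mean()
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite {objective} loss at epoch {epoch}; "
                    "check input scaling and learning rate")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.append(float(np.mean(losses)))
    emb = model.embed(views)
    emb.loss_history = history
    return model, emb


def train_ms_contab(
    views: FeatureViews,
    enc_params_g: EncoderParams | None = None,
    enc_params_c: EncoderParams | None = None,
    head_params: ProjectionHeadParams | None = None,
    cfg: TrainConfig | None = None,
) -> tuple[MsConTabModel, EmbeddingSet]:
    """Jointly train both TabNet encoders and heads under batch NT-Xent.

    Weight initialization, batch shuffling and the optimizer are all
    derived from ``cfg.seed``.  Raises on fewer than 3 cohorts (no
    meaningful negatives) or a non-finite loss.
    """
    cfg = cfg or TrainConfig()
    dg, dc = views.Xg.shape[1], views.Xc.shape[1]
    enc_params_g = enc_params_g or EncoderParams(input_dim=dg, seed=cfg.seed)
    enc_params_c = enc_params_c or EncoderParams(input_dim=dc, seed=cfg.seed + 1)
    head_params = head_params or ProjectionHeadParams(
        in_dim=enc_params_g.n_d, seed=cfg.seed + 2)
    head_params_c = ProjectionHeadParams(
        in_dim=enc_params_c.n_d, hidden_dim=head_params.hidden_dim,
        out_dim=head_params.out_dim, seed=head_params.seed + 1)
    return train_dual(
        views,
        TabNetEncoder(enc_params_g), TabNetEncoder(enc_params_c),
        ProjectionHead(head_params), ProjectionHead(head_params_c),
        cfg, objective="ntxent")
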