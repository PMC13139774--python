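"""Sequential-attention tabular encoder (TabNet-style).

The encoder processes a feature vector through several decision steps.  At
each step an attentive transformer produces a sparsemax attention mask over
the input features — a point on the probability simplex with exact zeros —
modulated by a prior that discounts features already used in earlier steps
(prior update: ``prior *= gamma - mask``).  The masked features pass through
a stack of GLU feature-transformer blocks (two shared across steps, two
step-specific), and the ReLU'd decision outputs are summed across steps
into the final latent representation (64-dim by default).

The per-step masks are retained as an interpretable trace: aggregated and
mapped back to named features they show which gene- or chromosome-level
substitution counts drove each cohort's embedding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, sparsemax_np

__all__ = ["EncoderParams", "TabNetEncoder", "sparsemax", "feature_importance"]

sparsemax = sparsemax_np  # public alias


@dataclass
class EncoderParams:
    """Architecture hyperparameters for one view's encoder.

    The latent width ``n_d`` doubles as the output dimension (64 keeps the
    embedding expressive yet compact for a few dozen cohorts).  ``gamma``
    relaxes feature reuse across steps: gamma=1 forces each feature to be
    used in at most one step, larger values allow reuse.
    """

    input_dim: int
    n_steps: int = 3
    n_d: int = 64
    n_a: int = 64
    gamma: float = 1.3
    n_shared: int = 2
    n_step_specific: int = 2
    normalization: str = "affine"  # "affine" (batch-statistics-free) or "batch"
    seed: int = 42

    def __post_init__(self):
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.gamma < 1.0:
            raise ValueError("gamma must be >= 1")
        if self.normalization not in {"affine", "batch"}:
            raise ValueError(f"unknown normalization {self.normalization!r}")


@dataclass
class AttentionMaskTrace:
    """Per-step sparsemax masks (each row on the simplex) and the decision
    weights used to aggregate them into feature importances."""

    masks: list[np.ndarray] = field(default_factory=list)
    step_weights: list[np.ndarray] = field(default_factory=list)


class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (n_in + n_out))
        self.W = Tensor(rng.normal(0.0, scale, size=(n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self):
        return [self.W, self.b]


class AffineNorm:
    """Per-feature trainable affine map (identity at init).

    Batch-statistics-free: stable with tiny batches and deterministic in
    evaluation, unlike batch normalization.
    """

    def __init__(self, n: int):
        self.g = Tensor(np.ones(n), requires_grad=True)
        self.b = Tensor(np.zeros(n), requires_grad=True)

    def __call__(self, x: Tensor, training: bool = True) -> Tensor:
        return x * self.g + self.b

    def parameters(self):
        return [self.g, self.b]


class BatchNorm:
    """Standard batch normalization (batch stats in training, running
    averages in evaluation)."""

    def __init__(self, n: int, momentum: float = 0.99, eps: float = 1e-5):
        self.g = Tensor(np.ones(n), requires_grad=True)
        self.b = Tensor(np.zeros(n), requires_grad=True)
        self.run_mean = np.zeros(n)
        self.run_var = np.ones(n)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, training: bool = True) -> Tensor:
        if training and x.data.shape[0] > 1:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) * (x - mu)).mean(axis=0, keepdims=True)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mu.data[0]
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var.data[0]
            xhat = (x - mu) / ((var + self.eps) ** 0.5)
        else:
            xhat = (x - Tensor(self.run_mean)) / Tensor(np.sqrt(self.run_var + self.eps))
        return xhat * self.g + self.b

    def parameters(self):
        return [self.g, self.b]


def _make_norm(kind: str, n: int):
    return AffineNorm(n) if kind == "affine" else BatchNorm(n)


class GLUBlock:
    """Linear -> normalization -> gated linear unit (a * sigmoid(b))."""

    def __init__(self, n_in: int, n_out: int, norm: str, rng: np.random.Generator):
        self.fc = Linear(n_in, 2 * n_out, rng)
        self.norm = _make_norm(norm, 2 * n_out)
        self.n_out = n_out

    def __call__(self, x: Tensor, training: bool = True) -> Tensor:
        h = self.norm(self.fc(x), training)
        return h.cols(0, self.n_out) * h.cols(self.n_out, 2 * self.n_out).sigmoid()

    def parameters(self):
        return self.fc.parameters() + self.norm.parameters()


class FeatureTransformer:
    """Shared + step-specific GLU blocks with sqrt(0.5)-scaled residuals."""

    SQRT_HALF = float(np.sqrt(0.5))

    def __init__(self, shared: list[GLUBlock], n_in: int, width: int,
                 n_specific: int, norm: str, rng: np.random.Generator):
        self.shared = shared
        self.specific = [GLUBlock(width, width, norm, rng) for _ in range(n_specific)]

    def __call__(self, x: Tensor, training: bool = True) -> Tensor:
        h = self.shared[0](x, training)
        for blk in self.shared[1:]:
            h = (h + blk(h, training)) * self.SQRT_HALF
        for blk in self.specific:
            h = (h + blk(h, training)) * self.SQRT_HALF
        return h

    def parameters(self):
        return [p for blk in self.specific for p in blk.parameters()]


class AttentiveTransformer:
    """Maps the previous step's attention features to a simplex mask."""

    def __init__(self, n_a: int, input_dim: int, norm: str, rng: np.random.Generator):
        self.fc = Linear(n_a, input_dim, rng)
        self.norm = _make_norm(norm, input_dim)

    def __call__(self, a: Tensor, prior: Tensor, training: bool = True) -> Tensor:
        return (self.norm(self.fc(a), training) * prior).sparsemax()

    def parameters(self):
        return self.fc.parameters() + self.norm.parameters()


class TabNetEncoder:
    """Encoder for one feature view; ``encode`` maps (batch, input_dim) to
    a (batch, n_d) latent plus the per-step attention-mask trace."""

    def __init__(self, params: EncoderParams):
        self.params = params
        rng = np.random.default_rng(params.seed)
        p = params
        width = p.n_d + p.n_a
        self.input_norm = _make_norm(p.normalization, p.input_dim)
        # shared GLU stack: first block consumes raw features
        self.shared_blocks = [GLUBlock(p.input_dim, width, p.normalization, rng)]
        for _ in range(p.n_shared - 1):
            self.shared_blocks.append(GLUBlock(width, width, p.normalization, rng))
        self.initial_ft = FeatureTransformer(
            self.shared_blocks, p.input_dim, width, p.n_step_specific, p.normalization, rng)
        self.step_fts = [
            FeatureTransformer(self.shared_blocks, p.input_dim, width,
                               p.n_step_specific, p.normalization, rng)
            for _ in range(p.n_steps)
        ]
        self.attentives = [
            AttentiveTransformer(p.n_a, p.input_dim, p.normalization, rng)
            for _ in range(p.n_steps)
        ]

    def parameters(self) -> list[Tensor]:
        params = self.input_norm.parameters()
        for blk in self.shared_blocks:
            params += blk.parameters()
        params += self.initial_ft.parameters()
        for ft in self.step_fts:
            params += ft.parameters()
        for at in self.attentives:
            params += at.parameters()
        return params

    def encode(self, X, training: bool = True) -> tuple[Tensor, AttentionMaskTrace]:
        """Run the decision steps; returns (latent H, mask trace).

        Deterministic given the weights: two calls with identical inputs
        and weights produce bit-identical outputs.
        """
        x = X if isinstance(X, Tensor) else Tensor(np.atleast_2d(X))
        if x.data.ndim != 2 or x.data.shape[1] != self.params.input_dim:
            raise ValueError(
                f"expected (batch, {self.params.input_dim}), got {x.data.shape}")
        p = self.params
        f = self.input_norm(x, training)
        prior = Tensor(np.ones_like(f.data))
        h0 = self.initial_ft(f, training)
        a = h0.cols(p.n_d, p.n_d + p.n_a)
        out = None
        trace = AttentionMaskTrace()
        for step in range(p.n_steps):
            mask = self.attentives[step](a, prior, training)
            prior = prior * (Tensor(p.gamma) - mask)
            h = self.step_fts[step]((f * mask), training)
            d = h.cols(0, p.n_d).relu()
            out = d if out is None else out + d
            a = h.cols(p.n_d, p.n_d + p.n_a)
            trace.masks.append(mask.data.copy())
            trace.step_weights.append(d.data.sum(axis=1).copy())
        return out, trace

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]


def feature_importance(trace: AttentionMaskTrace,
                       feature_names: list[str] | None = None):
    """Aggregate a mask trace into one importance vector per sample.

    Each step's mask is weighted by that step's total decision output (the
    summed ReLU activations), then the per-sample aggregate is normalized
    to sum to 1.  With a single step this reduces to the mask itself, and a
    feature masked to zero at every step gets importance exactly zero.
    """
    if not trace.masks:
        raise ValueError("empty attention trace")
    masks = np.stack(trace.masks)            # (steps, batch, features)
    weights = np.stack(trace.step_weights)   # (steps, batch)
    wsum = weights.sum(axis=0, keepdims=True)
    # degenerate all-zero decision outputs: fall back to uniform step weights
    weights = np.where(wsum > 0, weights, 1.0)
    agg = (masks * weights[:, :, None]).sum(axis=0)
    total = agg.sum(axis=1, keepdims=True)
    agg = np.where(total > 0, agg / np.where(total > 0, total, 1.0), 0.0)
    if feature_names is not None:
        import pandas as pd

        return pd.DataFrame(agg, columns=feature_names)
    return agg
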