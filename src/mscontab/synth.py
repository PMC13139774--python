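"""Synthetic COSMIC-shaped mutation cohorts with planted cluster structure.

The generator emits a flat somatic-SNV table (cohort, sample_id, gene,
chromosome, position, ref, alt) whose cohorts fall into a configurable
number of planted clusters.  Clusters differ jointly in the ways real
cancer groups do:

* **mutation burden** — cluster 0 carries a markedly higher load;
* **substitution bias** — cluster 0 is transition-heavy (C>T / G>A),
  cluster 1 flatter with elevated G>T transversions;
* **chromosome profile** — cluster 0 concentrates load on a few
  chromosomes (19, 7, 9, 1), cluster 1 is proportional to length;
* **gene propensities** — power-law over a 500-gene vocabulary with a
  shared high-propensity backbone (~60 % of top slots) plus
  cluster-specific driver genes.

Within-cluster cohort variation comes from Dirichlet perturbation of the
cluster profiles plus multinomial sampling noise.  Every knob is an
independent config field so tests can isolate each signal, and a
``separation_dial`` interpolates all cluster profiles toward their common
mean (level 0 = identical clusters, a true null; level 1 = the configured
separation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .records import CANONICAL_CHROMOSOMES, MutationRecord
from .signatures import GRCH38_LENGTHS, N_SUBSTITUTIONS, SUBSTITUTIONS

__all__ = ["SynthConfig", "SynthDataset", "generate_dataset", "separation_dial"]

_PAIRS = [s.split(">") for s in SUBSTITUTIONS]


def _default_sub_bias(n_clusters: int) -> np.ndarray:
    """Cluster substitution biases: cluster 0 transition-heavy, cluster 1
    flat with elevated G>T; further clusters interpolate."""
    base = np.ones(N_SUBSTITUTIONS)
    heavy = base.copy()
    heavy[SUBSTITUTIONS.index("C>T")] = 8.0
    heavy[SUBSTITUTIONS.index("G>A")] = 6.0
    flat = base.copy()
    flat[SUBSTITUTIONS.index("G>T")] = 3.0
    profiles = [heavy, flat]
    while len(profiles) < n_clusters:
        t = len(profiles) / (n_clusters)
        profiles.append(heavy * (1 - t) + flat * t)
    P = np.stack(profiles[:n_clusters])
    return P / P.sum(axis=1, keepdims=True)


def _default_chrom_profile(n_clusters: int) -> np.ndarray:
    lengths = np.array([GRCH38_LENGTHS[c] for c in CANONICAL_CHROMOSOMES], float)
    flat = lengths / lengths.sum()
    hot = flat.copy()
    for c, mult in {"19": 3.0, "7": 1.8, "9": 1.8, "1": 1.8}.items():
        hot[CANONICAL_CHROMOSOMES.index(c)] *= mult
    hot /= hot.sum()
    profiles = [hot, flat]
    while len(profiles) < n_clusters:
        profiles.append(flat)
    return np.stack(profiles[:n_clusters])


def _default_gene_probs(n_clusters: int, vocab_size: int,
                        shared_frac: float = 0.6, top: int = 25,
                        power: float = 1.0) -> np.ndarray:
    """Power-law gene propensities with a shared top-gene backbone.

    The first ``shared_frac * top`` high-propensity slots are the same
    genes in every cluster; the remaining top slots are cluster-specific.
    """
    weights = 1.0 / np.arange(1, vocab_size + 1) ** power
    n_shared = int(round(shared_frac * top))
    n_unique = top - n_shared
    profiles = []
    for c in range(n_clusters):
        order = np.empty(vocab_size, dtype=int)
        order[:n_shared] = np.arange(n_shared)
        uniq_start = n_shared + c * n_unique
        order[n_shared:top] = np.arange(uniq_start, uniq_start + n_unique)
        used = set(order[:top].tolist())
        order[top:] = [g for g in range(vocab_size) if g not in used]
        p = np.empty(vocab_size)
        p[order] = weights
        profiles.append(p / p.sum())
    return np.stack(profiles)


@dataclass
class SynthConfig:
    """Generator parameters; per-cluster profile arrays are derived from
    the scalar knobs at construction unless given explicitly."""

    n_cohorts: int = 40
    n_clusters: int = 2
    proportions: tuple[float, ...] | None = None
    vocab_size: int = 500
    top_genes: int = 25
    shared_top_frac: float = 0.6
    burden: tuple[float, ...] | None = None          # mean mutations per cohort
    samples_per_cohort: int = 50
    sub_concentration: float = 150.0                 # Dirichlet conc, 12-dim bias
    gene_concentration: float = 5000.0               # Dirichlet conc, gene probs
    seed: int = 42
    # derived (or explicitly supplied) per-cluster profiles
    gene_probs: np.ndarray | None = None             # (n_clusters, vocab_size)
    sub_bias: np.ndarray | None = None               # (n_clusters, 12)
    chrom_profile: np.ndarray | None = None          # (n_clusters, 24)

    def __post_init__(self):
        k = self.n_clusters
        if self.proportions is None:
            self.proportions = tuple([1.0 / k] * k)
        if abs(sum(self.proportions) - 1.0) > 1e-9 or len(self.proportions) != k:
            raise ValueError("proportions must be length n_clusters and sum to 1")
        if self.burden is None:
            self.burden = tuple((3000.0, 1200.0) + (1500.0,) * (k - 2))[:k]
        if any(b <= 0 for b in self.burden):
            raise ValueError("burden must be positive")
        if self.gene_probs is None:
            self.gene_probs = _default_gene_probs(
                k, self.vocab_size, self.shared_top_frac, self.top_genes)
        if self.sub_bias is None:
            self.sub_bias = _default_sub_bias(k)
        if self.chrom_profile is None:
            self.chrom_profile = _default_chrom_profile(k)
        for name in ("gene_probs", "sub_bias", "chrom_profile"):
            arr = getattr(self, name)
            if np.any(arr < 0) or not np.allclose(arr.sum(axis=1), 1.0):
                raise ValueError(f"{name} rows must be probability vectors")


@dataclass
class SynthDataset:
    records: list[MutationRecord]
    true_labels: dict[str, int]
    config: SynthConfig = field(repr=False, default=None)

    def labels_array(self, cohorts: list[str]) -> np.ndarray:
        return np.array([self.true_labels[c] for c in cohorts])

    def write(self, out_dir: str | Path) -> None:
        from .records import write_mutation_table

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_mutation_table(self.records, out / "mutations.tsv")
        pd.DataFrame(
            sorted(self.true_labels.items()), columns=["cohort", "cluster"]
        ).to_csv(out / "true_labels.csv", index=False)


def _cohort_labels(cfg: SynthConfig) -> list[int]:
    """Deterministic label assignment matching the configured proportions."""
    counts = [int(round(p * cfg.n_cohorts)) for p in cfg.proportions]
    while sum(counts) > cfg.n_cohorts:
        counts[int(np.argmax(counts))] -= 1
    while sum(counts) < cfg.n_cohorts:
        counts[int(np.argmin(counts))] += 1
    labels = [c for c, n in enumerate(counts) for _ in range(n)]
    return labels


def generate_dataset(cfg: SynthConfig | None = None) -> SynthDataset:
    """Draw the full mutation table; identical config + seed gives an
    identical table."""
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    lengths = np.array([GRCH38_LENGTHS[c] for c in CANONICAL_CHROMOSOMES])
    labels = _cohort_labels(cfg)
    width = len(str(cfg.n_cohorts - 1))
    records: list[MutationRecord] = []
    true_labels: dict[str, int] = {}
    gene_names = [f"G{g:03d}" for g in range(cfg.vocab_size)]
    for i, cl in enumerate(labels):
        cohort = f"C{i:0{width}d}"
        true_labels[cohort] = cl
        n_mut = max(1, int(rng.poisson(cfg.burden[cl])))
        gene_p = rng.dirichlet(cfg.gene_concentration * cfg.gene_probs[cl]
                               + 1e-9)
        sub_p = rng.dirichlet(cfg.sub_concentration * cfg.sub_bias[cl] + 1e-9)
        genes = rng.choice(cfg.vocab_size, size=n_mut, p=gene_p)
        subs = rng.choice(N_SUBSTITUTIONS, size=n_mut, p=sub_p)
        chroms = rng.choice(len(CANONICAL_CHROMOSOMES), size=n_mut,
                            p=cfg.chrom_profile[cl])
        samples = rng.integers(0, cfg.samples_per_cohort, size=n_mut)
        positions = rng.integers(1, lengths[chroms] + 1)
        for g, s, ch, sm, pos in zip(genes, subs, chroms, samples, positions):
            ref, alt = _PAIRS[s]
            records.append(MutationRecord(
                cohort=cohort, sample_id=f"{cohort}_S{sm:03d}",
                gene=gene_names[g], chromosome=CANONICAL_CHROMOSOMES[ch],
                position=int(pos), ref=ref, alt=alt))
    return SynthDataset(records=records, true_labels=true_labels, config=cfg)


def separation_dial(cfg: SynthConfig, level: float) -> SynthConfig:
    """Interpolate every cluster profile toward the across-cluster mean.

    level 1 returns the config unchanged; level 0 collapses all clusters
    onto one common profile (a true null for recovery tests).
    """
    if not 0.0 <= level <= 1.0:
        raise ValueError("level must be in [0, 1]")
    w = np.asarray(cfg.proportions)

    def mix(P: np.ndarray) -> np.ndarray:
        mean = (w[:, None] * P).sum(axis=0)
        return mean[None, :] + level * (P - mean[None, :])

    burden = np.asarray(cfg.burden, float)
    burden_mixed = tuple(float(b) for b in
                         (w * burden).sum() + level * (burden - (w * burden).sum()))
    return replace(
        cfg,
        burden=burden_mixed,
        gene_probs=mix(cfg.gene_probs),
        sub_bias=mix(cfg.sub_bias),
        chrom_profile=mix(cfg.chrom_profile),
    )
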