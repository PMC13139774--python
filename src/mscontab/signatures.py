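"""Per-cohort mutation-signature views.

Each cancer cohort is summarized by two complementary tabular views built
from its filtered coding SNVs:

* a **gene-level signature**: counts of the 12 ordered single-nucleotide
  substitution categories for the cohort's 25 most frequently mutated
  genes, flattened row-major to a 300-vector;
* a **chromosome-level signature**: the same 12 categories tallied per
  canonical chromosome (1..22, X, Y) and divided by chromosome length in
  bp, flattened to a 288-vector.

The 12 categories are the ordered, strand-specific pairs (ref, alt) over
{A,C,G,T} in lexicographic order — complementary substitutions such as
C>T and G>A are kept separate because their loads genuinely differ across
cancer groups.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .records import BASES, CANONICAL_CHROMOSOMES, MutationRecord

#: the 12 ordered substitutions in fixed lexicographic order
SUBSTITUTIONS: tuple[str, ...] = tuple(
    f"{r}>{a}" for r, a in itertools.product("ACGT", repeat=2) if r != a
)
N_SUBSTITUTIONS = 12
DEFAULT_TOP_K = 25
GENE_VIEW_DIM = DEFAULT_TOP_K * N_SUBSTITUTIONS        # 300
CHROM_VIEW_DIM = len(CANONICAL_CHROMOSOMES) * N_SUBSTITUTIONS  # 288

_SUB_INDEX = {s: i for i, s in enumerate(SUBSTITUTIONS)}
_CHROM_INDEX = {c: i for i, c in enumerate(CANONICAL_CHROMOSOMES)}

#: GRCh38 primary-assembly chromosome lengths (bp)
GRCH38_LENGTHS: dict[str, int] = {
    "1": 248956422, "2": 242193529, "3": 198295559, "4": 190214555,
    "5": 181538259, "6": 170805979, "7": 159345973, "8": 145138636,
    "9": 138394717, "10": 133797422, "11": 135086622, "12": 133275309,
    "13": 114364328, "14": 107043718, "15": 101991189, "16": 90338345,
    "17": 83257441, "18": 80373285, "19": 58617616, "20": 64444167,
    "21": 46709983, "22": 50818468, "X": 156040895, "Y": 57227415,
}


def substitution_index(ref: str, alt: str) -> int:
    """Index of an ordered substitution in the fixed 12-category order."""
    if ref not in BASES or alt not in BASES:
        raise ValueError(f"bases must be in ACGT, got {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError(f"not a substitution: {ref}>{alt}")
    return _SUB_INDEX[f"{ref}>{alt}"]


def load_chrom_lengths(path: str | Path | None = None) -> dict[str, int]:
    """Chromosome-length table; default is GRCh38, overridable by a
    2-column TSV (chromosome, length_bp) covering all 24 labels."""
    if path is None:
        return dict(GRCH38_LENGTHS)
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    table = {str(c).strip(): int(l) for c, l in zip(df.iloc[:, 0], df.iloc[:, 1])}
    missing = [c for c in CANONICAL_CHROMOSOMES if c not in table]
    if missing:
        raise ValueError(f"chromosome length table missing: {missing}")
    if any(v <= 0 for v in table.values()):
        raise ValueError("chromosome lengths must be positive")
    return {c: table[c] for c in CANONICAL_CHROMOSOMES}


@dataclass
class GeneSignature:
    """Top-k gene x 12-substitution count matrix for one cohort."""

    cohort: str
    genes: list[str]
    matrix: np.ndarray  # (top_k, 12) integer counts, zero-padded rows

    @property
    def x(self) -> np.ndarray:
        return self.matrix.reshape(-1)


@dataclass
class ChromosomeSignature:
    """24-chromosome x 12-substitution length-normalized rate matrix."""

    cohort: str
    matrix: np.ndarray  # (24, 12) counts / chromosome length

    @property
    def x(self) -> np.ndarray:
        return self.matrix.reshape(-1)


def top_genes(records: list[MutationRecord], top_k: int = DEFAULT_TOP_K) -> list[str]:
    """Genes ranked by descending mutation count, ties broken alphabetically."""
    counts: dict[str, int] = {}
    for r in records:
        counts[r.gene] = counts.get(r.gene, 0) + 1
    ranked = sorted(counts, key=lambda g: (-counts[g], g))
    return ranked[:top_k]


def build_gene_signature(
    records: list[MutationRecord],
    top_k: int = DEFAULT_TOP_K,
    cohort: str | None = None,
) -> GeneSignature:
    """Tally the 12 substitution categories for the cohort's top-k genes.

    Cohorts with fewer than ``top_k`` mutated genes are zero-padded so the
    flattened vector always has length ``top_k * 12``.
    """
    if cohort is None:
        cohort = records[0].cohort if records else ""
    genes = top_genes(records, top_k)
    gene_row = {g: i for i, g in enumerate(genes)}
    matrix = np.zeros((top_k, N_SUBSTITUTIONS), dtype=float)
    for r in records:
        i = gene_row.get(r.gene)
        if i is not None:
            matrix[i, substitution_index(r.ref, r.alt)] += 1
    return GeneSignature(cohort=cohort, genes=genes, matrix=matrix)


def build_chromosome_signature(
    records: list[MutationRecord],
    lengths: dict[str, int] | None = None,
    restrict_to_top_genes: bool = False,
    top_k: int = DEFAULT_TOP_K,
    cohort: str | None = None,
) -> ChromosomeSignature:
    """Per-chromosome substitution counts divided by chromosome length.

    By default every retained coding SNV of the cohort is counted;
    ``restrict_to_top_genes`` limits the tally to the cohort's top-k genes
    (the alternative reading of which mutation population feeds this view).
    """
    if lengths is None:
        lengths = GRCH38_LENGTHS
    if cohort is None:
        cohort = records[0].cohort if records else ""
    if restrict_to_top_genes:
        keep = set(top_genes(records, top_k))
        records = [r for r in records if r.gene in keep]
    matrix = np.zeros((len(CANONICAL_CHROMOSOMES), N_SUBSTITUTIONS), dtype=float)
    for r in records:
        i = _CHROM_INDEX.get(r.chromosome)
        if i is None:
            raise ValueError(f"non-canonical chromosome {r.chromosome!r}; filter first")
        matrix[i, substitution_index(r.ref, r.alt)] += 1
    length_vec = np.array([lengths[c] for c in CANONICAL_CHROMOSOMES], dtype=float)
    return ChromosomeSignature(cohort=cohort, matrix=matrix / length_vec[:, None])


# ---------------------------------------------------------------------------
# assembled feature views + scaling


@dataclass
class ViewScaler:
    """Scaling of a signature view before encoding.

    Two methods, both log1p-based and invertible on the training set:

    * ``"log1p_global"`` (default) — multiply by ``pre_factor`` (used to
      express chromosome rates per Mb), log1p, then subtract the view's
      global mean and divide by its global standard deviation.  Relative
      per-feature variances are preserved, so the burden and spectrum
      amplitudes that distinguish cancer groups survive scaling.
    * ``"log1p_zscore"`` — log1p then per-feature standardization across
      cohorts; constant features are mapped to 0 (their std is treated
      as 1).  Whitens every feature to equal variance, which also
      amplifies pure sampling noise — kept as an option.
    """

    method: str = "log1p_global"
    pre_factor: float = 1.0
    mean: np.ndarray | None = None
    std: np.ndarray | None = None
    constant_mask: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "ViewScaler":
        L = np.log1p(X * self.pre_factor)
        if self.method == "log1p_global":
            self.mean = np.asarray(L.mean())
            std = float(L.std())
            self.std = np.asarray(std if std > 0 else 1.0)
            self.constant_mask = None
        elif self.method == "log1p_zscore":
            self.mean = L.mean(axis=0)
            std = L.std(axis=0)
            # relative threshold: a column constant up to rounding is
            # degenerate and maps to exactly 0
            self.constant_mask = std <= 1e-12 * np.maximum(1.0, np.abs(self.mean))
            self.std = np.where(self.constant_mask, 1.0, std)
        else:
            raise ValueError(f"unknown scaling method {self.method!r}")
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean is None:
            raise RuntimeError("scaler not fitted")
        Z = (np.log1p(X * self.pre_factor) - self.mean) / self.std
        if self.constant_mask is not None and self.constant_mask.any():
            Z[..., self.constant_mask] = 0.0
        return Z

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        return np.expm1(Z * self.std + self.mean) / self.pre_factor


@dataclass
class FeatureViews:
    """Aligned per-cohort feature matrices for the two views.

    ``Xg_raw`` / ``Xc_raw`` keep the untransformed counts and rates (needed
    for cluster spectra and the non-negative NMF baseline); ``Xg`` / ``Xc``
    are the scaled encoder inputs.
    """

    cohorts: list[str]
    Xg_raw: np.ndarray
    Xc_raw: np.ndarray
    Xg: np.ndarray
    Xc: np.ndarray
    gene_signatures: dict[str, GeneSignature] = field(default_factory=dict)
    chrom_signatures: dict[str, ChromosomeSignature] = field(default_factory=dict)
    scaler_g: ViewScaler | None = None
    scaler_c: ViewScaler | None = None

    @property
    def n_cohorts(self) -> int:
        return len(self.cohorts)


def assemble_feature_views(
    gene_sigs: dict[str, GeneSignature],
    chrom_sigs: dict[str, ChromosomeSignature],
    scale: bool = True,
    scaling: str = "log1p_global",
) -> FeatureViews:
    """Stack per-cohort signatures into aligned matrices and fit the scaler.

    Cohort order is sorted for determinism; a cohort present in only one
    view is an error.  Chromosome rates are expressed per Mb before the
    log transform so both views live on comparable numeric ranges.
    """
    if set(gene_sigs) != set(chrom_sigs):
        only_g = sorted(set(gene_sigs) - set(chrom_sigs))
        only_c = sorted(set(chrom_sigs) - set(gene_sigs))
        raise ValueError(f"cohort mismatch between views: {only_g} vs {only_c}")
    cohorts = sorted(gene_sigs)
    Xg_raw = np.stack([gene_sigs[c].x for c in cohorts])
    Xc_raw = np.stack([chrom_sigs[c].x for c in cohorts])
    if scale:
        sg = ViewScaler(method=scaling).fit(Xg_raw)
        sc = ViewScaler(method=scaling, pre_factor=1e6).fit(Xc_raw)
        Xg, Xc = sg.transform(Xg_raw), sc.transform(Xc_raw)
    else:
        sg = sc = None
        Xg, Xc = Xg_raw.copy(), Xc_raw.copy()
    return FeatureViews(
        cohorts=cohorts, Xg_raw=Xg_raw, Xc_raw=Xc_raw, Xg=Xg, Xc=Xc,
        gene_signatures=dict(gene_sigs), chrom_signatures=dict(chrom_sigs),
        scaler_g=sg, scaler_c=sc,
    )


def build_feature_views(
    records: list[MutationRecord],
    lengths: dict[str, int] | None = None,
    top_k: int = DEFAULT_TOP_K,
    restrict_to_top_genes: bool = False,
    scale: bool = True,
    scaling: str = "log1p_global",
) -> FeatureViews:
    """Group filtered records by cohort and build both signature views."""
    by_cohort: dict[str, list[MutationRecord]] = {}
    for r in records:
        by_cohort.setdefault(r.cohort, []).append(r)
    gene_sigs = {
        c: build_gene_signature(rs, top_k=top_k, cohort=c)
        for c, rs in by_cohort.items()
    }
    chrom_sigs = {
        c: build_chromosome_signature(
            rs, lengths=lengths, restrict_to_top_genes=restrict_to_top_genes,
            top_k=top_k, cohort=c,
        )
        for c, rs in by_cohort.items()
    }
    return assemble_feature_views(gene_sigs, chrom_sigs, scale=scale,
                                  scaling=scaling)


def gene_feature_names(top_k: int = DEFAULT_TOP_K) -> list[str]:
    """Column names for the flattened gene view: ``gene_rank{i}|{sub}``."""
    return [f"gene_rank{i + 1}|{s}" for i in range(top_k) for s in SUBSTITUTIONS]


def chrom_feature_names() -> list[str]:
    return [f"chr{c}|{s}" for c in CANONICAL_CHROMOSOMES for s in SUBSTITUTIONS]


def export_views_csv(views: FeatureViews, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    top_k = views.Xg_raw.shape[1] // N_SUBSTITUTIONS
    pd.DataFrame(views.Xg_raw, index=views.cohorts,
                 columns=gene_feature_names(top_k)).to_csv(out / "gene_view.csv")
    pd.DataFrame(views.Xc_raw, index=views.cohorts,
                 columns=chrom_feature_names()).to_csv(out / "chromosome_view.csv")
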