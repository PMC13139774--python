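"""End-to-end orchestration: filter -> featurize -> train -> cluster ->
evaluate, driven by one validated config, with a checksummed artifact
manifest and per-stage resume."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import cluster as ce
from .contrastive import TrainConfig, train_ms_contab
from .records import filter_records, read_mutation_table, write_mutation_table
from .signatures import build_feature_views, export_views_csv, load_chrom_lengths
from .synth import SynthConfig, generate_dataset

log = logging.getLogger("mscontab")

_SCHEMA: dict[str, set[str]] = {
    "paths": {"input_table", "chrom_lengths", "output_dir"},
    "synth": {"enabled", "n_cohorts", "n_clusters", "separation", "seed",
              "burden", "samples_per_cohort"},
    "filter": {"rules", "dedup"},
    "signatures": {"top_k", "restrict_to_top_genes"},
    "train": {"epochs", "learning_rate", "batch_size", "temperature", "seed",
              "fusion_mode", "denominator"},
    "clustering": {"k", "n_init", "seed"},
    "projection": {"method", "seed"},
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    raw: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        for section, keys in d.items():
            if section not in _SCHEMA:
                raise ValueError(f"unknown config section {section!r}")
            if not isinstance(keys, dict):
                raise ValueError(f"config section {section!r} must be a mapping")
            unknown = set(keys) - _SCHEMA[section]
            if unknown:
                raise ValueError(
                    f"unknown config key(s) in {section!r}: {sorted(unknown)}")
        return cls(raw=d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def get(self, section: str, key: str, default=None):
        return self.raw.get(section, {}).get(key, default)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig, resume: bool = False) -> dict:
    """Execute every stage, writing artifacts and a manifest to the output
    directory.  With ``resume=True`` a stage whose artifacts already exist
    is skipped (deterministic stages reproduce identical checksums)."""
    out = Path(cfg.get("paths", "output_dir", "ms_contab_out"))
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict] = {}

    def record(stage: str, *paths: Path):
        for p in paths:
            manifest[p.name] = {"file": str(p), "stage": stage,
                                "sha256": _sha256(p)}

    def fresh(*paths: Path) -> bool:
        return not (resume and all(p.exists() for p in paths))

    # -- stage: synth / input -------------------------------------------------
    table = cfg.get("paths", "input_table")
    if table is None:
        if not cfg.get("synth", "enabled", True):
            raise RuntimeError("stage synth: no input_table and synth disabled")
        synth_cfg = SynthConfig(
            n_cohorts=int(cfg.get("synth", "n_cohorts", 40)),
            n_clusters=int(cfg.get("synth", "n_clusters", 2)),
            samples_per_cohort=int(cfg.get("synth", "samples_per_cohort", 50)),
            seed=int(cfg.get("synth", "seed", 42)),
        )
        sep = float(cfg.get("synth", "separation", 1.0))
        if sep < 1.0:
            from .synth import separation_dial

            synth_cfg = separation_dial(synth_cfg, sep)
        table = out / "mutations.tsv"
        if fresh(table):
            log.info("stage synth: generating %d cohorts", synth_cfg.n_cohorts)
            ds = generate_dataset(synth_cfg)
            ds.write(out)
        record("synth", table, out / "true_labels.csv")
    table = Path(table)

    # -- stage: filter --------------------------------------------------------
    filtered_path = out / "filtered.tsv"
    report_path = out / "filter_report.json"
    if fresh(filtered_path, report_path):
        log.info("stage filter: %s", table)
        records = read_mutation_table(table)
        if cfg.get("filter", "dedup", False):
            from .records import dedup_records

            records = dedup_records(records)
        rules = cfg.get("filter", "rules")
        retained, report = filter_records(
            records, set(rules) if rules else None)
        write_mutation_table(retained, filtered_path)
        report.to_json(report_path)
    record("filter", filtered_path, report_path)

    # -- stage: featurize -----------------------------------------------------
    gene_csv = out / "gene_view.csv"
    chrom_csv = out / "chromosome_view.csv"
    retained = read_mutation_table(filtered_path)
    retained, _ = filter_records(retained)
    lengths = load_chrom_lengths(cfg.get("paths", "chrom_lengths"))
    views = build_feature_views(
        retained, lengths=lengths,
        top_k=int(cfg.get("signatures", "top_k", 25)),
        restrict_to_top_genes=bool(
            cfg.get("signatures", "restrict_to_top_genes", False)),
    )
    if fresh(gene_csv, chrom_csv):
        log.info("stage featurize: %d cohorts", views.n_cohorts)
        export_views_csv(views, out)
    record("featurize", gene_csv, chrom_csv)

    # -- stage: train ---------------------------------------------------------
    train_cfg = TrainConfig(
        epochs=int(cfg.get("train", "epochs", 100)),
        learning_rate=float(cfg.get("train", "learning_rate", 1e-3)),
        batch_size=int(cfg.get("train", "batch_size", 8)),
        temperature=float(cfg.get("train", "temperature", 0.5)),
        seed=int(cfg.get("train", "seed", 42)),
        fusion_mode=cfg.get("train", "fusion_mode", "mean"),
        denominator=cfg.get("train", "denominator", "anchor"),
    )
    emb_csv = out / "embeddings.csv"
    loss_csv = out / "loss_history.csv"
    log.info("stage train: %d epochs", train_cfg.epochs)
    model, emb = train_ms_contab(views, cfg=train_cfg)
    if fresh(emb_csv, loss_csv):
        emb.to_csv(emb_csv)
        import pandas as pd

        pd.DataFrame({"epoch": range(1, len(emb.loss_history) + 1),
                      "mean_loss": emb.loss_history}).to_csv(loss_csv, index=False)
        model.save(out / "checkpoint")
    record("train", emb_csv, loss_csv)

    # -- stage: cluster -------------------------------------------------------
    k = int(cfg.get("clustering", "k", 2))
    result = ce.kmeans_cluster(
        emb.Z_fused, k=k, seed=int(cfg.get("clustering", "seed", 42)),
        n_init=int(cfg.get("clustering", "n_init", 10)), cohorts=emb.cohorts)
    clusters_csv = out / "clusters.csv"
    if fresh(clusters_csv):
        log.info("stage cluster: k=%d", k)
        result.to_frame().to_csv(clusters_csv, index=False)
    record("cluster", clusters_csv)

    # -- stage: evaluate ------------------------------------------------------
    metrics_json = out / "metrics.json"
    sim_csv = out / "similarity_matrix.csv"
    nn_csv = out / "neighbors.csv"
    overlap_json = out / "gene_overlap.json"
    spectra_csv = out / "spectra.csv"
    imp_g_csv = out / "gene_importance.csv"
    imp_c_csv = out / "chromosome_importance.csv"
    if fresh(imp_g_csv, imp_c_csv):
        from .signatures import chrom_feature_names, gene_feature_names
        from .tabnet import feature_importance

        trace_g, trace_c = model.mask_traces(views)
        top_k = views.Xg_raw.shape[1] // 12
        for trace, names, path in (
            (trace_g, gene_feature_names(top_k), imp_g_csv),
            (trace_c, chrom_feature_names(), imp_c_csv),
        ):
            df = feature_importance(trace, feature_names=names)
            df.insert(0, "cohort", views.cohorts)
            df.to_csv(path, index=False)
    record("evaluate", imp_g_csv, imp_c_csv)
    if fresh(metrics_json, sim_csv, nn_csv, overlap_json, spectra_csv):
        log.info("stage evaluate")
        orig = ce.internal_metrics(emb.Z_fused, result.labels, "original")
        proj_method = cfg.get("projection", "method", "umap")
        coords = ce.project_2d(emb.Z_fused, method=proj_method,
                               seed=int(cfg.get("projection", "seed", 42)))
        proj = ce.internal_metrics(coords, result.labels, "projected_2d")
        payload = {
            "original": orig.as_dict(), "projected_2d": proj.as_dict(),
            "projection_method": proj_method,
            "within_between": ce.within_between_similarity(
                emb.Z_fused, result.labels),
            "prototypes": {str(k_): v for k_, v in ce.cluster_prototypes(
                emb.Z_fused, result.labels, emb.cohorts).items()},
        }
        metrics_json.write_text(json.dumps(payload, indent=2))
        ce.cosine_matrix(emb.Z_fused, emb.cohorts, result.labels).to_csv(sim_csv)
        ce.nearest_neighbors(emb.Z_fused, emb.cohorts).to_csv(nn_csv, index=False)
        labels_map = dict(zip(emb.cohorts, (int(l) for l in result.labels)))
        spectra = ce.cluster_spectra(
            views.gene_signatures, views.chrom_signatures, labels_map)
        spectra.substitution_means.join(
            spectra.chromosome_means).to_csv(spectra_csv)
        sets = ce.cluster_gene_sets(views.gene_signatures, labels_map)
        if len(sets) == 2:
            a, b = (sets[c] for c in sorted(sets))
            overlap_json.write_text(json.dumps(ce.gene_set_overlap(a, b),
                                               indent=2))
        else:
            overlap_json.write_text(json.dumps(
                {c: sorted(s) for c, s in sets.items()}, indent=2))
    record("evaluate", metrics_json, sim_csv, nn_csv, overlap_json, spectra_csv)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
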