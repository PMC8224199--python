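"""End-to-end orchestration: simulate/load -> preprocess -> scan -> concordance
-> community -> transfer, with TSV/JSON outputs and a reproducibility manifest.

Every stage is a pure function of (inputs, config, seed); re-running the same
configuration reproduces all outputs bit-identically.  The manifest records
the config hash, package version, master seed and per-stage row counts (no
timestamps, so manifests from identical runs compare equal).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .community import bray_curtis, pcoa, permanova, shannon
from .concordance import cluster_signature, concordance_analysis
from .errors import ValidationError
from .lmm import DEFAULT_P_FLOOR, panel_scan, signature_scan
from .ml import TRANSFER_COLUMNS, labels_from_meta, loso, transfer_matrix
from .preprocess import (DEFAULT_PREVALENCE, DEFAULT_PSEUDOCOUNT, log_pathway,
                         normalize_depth, prevalence_filter)
from .synthetic import SyntheticConfig, simulate_multistudy
from .tables import (FeatureTable, SampleMetadata, align, read_feature_table,
                     read_metadata, write_feature_table, write_metadata,
                     write_result_table)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated run configuration (YAML-serializable)."""

    seed: int
    synthetic: dict | None = None          # SyntheticConfig fields
    studies: list[dict] | None = None      # [{table: path, metadata: path}, ...]
    prevalence_threshold: float = DEFAULT_PREVALENCE
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    p_floor: float = DEFAULT_P_FLOOR
    pathway_mode: bool = False
    n_perm: int = 999
    model: str = "lasso"
    k: int = 8
    repeats: int = 10
    panel: list[str] = field(default_factory=list)
    threads: int = 1

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.studies is None):
            raise ValidationError(
                "config must provide exactly one of 'synthetic' or 'studies'"
            )
        if self.seed is None:
            raise ValidationError("seed is mandatory")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in raw:
            raise ValidationError("config must set 'seed'")
        return cls(**raw)

    def canonical(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, default=str)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]

    def provenance(self) -> dict:
        return {"cohortsig_version": __version__, "config_hash": self.config_hash()}


def _synthetic_config(cfg: RunConfig) -> SyntheticConfig:
    params = dict(cfg.synthetic or {})
    params.setdefault("seed", cfg.seed)
    return SyntheticConfig(**params)


def stage_simulate(cfg: RunConfig, outdir: Path) -> list[tuple[FeatureTable, SampleMetadata]]:
    studies = simulate_multistudy(_synthetic_config(cfg))
    for table, meta in studies:
        sid = meta.frame["study_id"].iloc[0]
        write_feature_table(table, outdir / f"{sid}_counts.tsv",
                            comments=[f"{k}={v}" for k, v in cfg.provenance().items()])
        write_metadata(meta, outdir / f"{sid}_metadata.tsv")
    return studies


def load_studies(cfg: RunConfig, outdir: Path) -> list[tuple[FeatureTable, SampleMetadata]]:
    """Load input studies: from configured paths, or from a prior simulate stage."""
    if cfg.studies is not None:
        out = []
        for entry in cfg.studies:
            table = read_feature_table(entry["table"])
            meta = read_metadata(entry["metadata"])
            out.append(align(table, meta))
        return out
    existing = sorted(outdir.glob("S*_counts.tsv"))
    if existing:
        out = []
        for counts_path in existing:
            sid = counts_path.name.removesuffix("_counts.tsv")
            table = read_feature_table(counts_path)
            meta = read_metadata(outdir / f"{sid}_metadata.tsv")
            out.append(align(table, meta))
        return out
    return stage_simulate(cfg, outdir)


def preprocess_study(table: FeatureTable, cfg: RunConfig):
    """Prevalence filter then depth normalization (or log transform for pathways)."""
    filtered = prevalence_filter(table, cfg.prevalence_threshold)
    if cfg.pathway_mode:
        return log_pathway(filtered)
    return normalize_depth(filtered)


def stage_scan(studies, cfg: RunConfig, outdir: Path) -> pd.DataFrame:
    sigs = []
    for table, meta in studies:
        normalized = preprocess_study(table, cfg)
        sigs.append(signature_scan(normalized, meta, p_floor=cfg.p_floor,
                                   n_jobs=cfg.threads))
        if cfg.panel:
            sid = meta.frame["study_id"].iloc[0]
            try:
                panel_sig = panel_scan(normalized, meta, cfg.panel, p_floor=cfg.p_floor)
            except ValidationError as exc:
                logger.warning("panel scan skipped for %s: %s", sid, exc)
            else:
                write_result_table(panel_sig, outdir / f"panel_{sid}.tsv",
                                   cfg.provenance())
    signatures = pd.concat(sigs, ignore_index=True)
    write_result_table(signatures, outdir / "signatures.tsv", cfg.provenance())
    return signatures


def stage_concord(signatures: pd.DataFrame, cfg: RunConfig, outdir: Path):
    results, tidy, summary = concordance_analysis(signatures)
    write_result_table(tidy, outdir / "concordance.tsv", cfg.provenance())
    with open(outdir / "concordance_summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    wide = signatures.pivot_table(
        index="feature_id", columns=["study_id", "timepoint_months"],
        values="signed_log10p",
    )
    clust = cluster_signature(wide)
    meta = dict(cfg.provenance())
    meta["linkage"] = "complete"
    meta["distance"] = "euclidean"
    order = pd.DataFrame({"feature_id": clust.row_order})
    write_result_table(order, outdir / "signature_cluster_order.tsv", meta)
    return tidy, summary


def _joined_normalized(studies, cfg: RunConfig) -> tuple[FeatureTable, SampleMetadata]:
    """Per-study normalized tables joined on the union of features (absent -> 0)."""
    norm = [(preprocess_study(t, cfg), m) for t, m in studies]
    features = sorted(set().union(*(n.values.index for n, _ in norm)))
    joined = pd.concat(
        [n.values.reindex(features, fill_value=0.0) for n, _ in norm], axis=1
    )
    meta = SampleMetadata(pd.concat([m.frame for _, m in norm], ignore_index=True))
    return FeatureTable(joined, is_count=False), meta


def stage_community(studies, cfg: RunConfig, outdir: Path):
    joined, meta = _joined_normalized(studies, cfg)
    dist = bray_curtis(joined)
    ordination = pcoa(dist)
    coords = ordination.coordinates.rename_axis("sample_id").reset_index()
    meta_info = dict(cfg.provenance())
    meta_info["eigenvalues"] = ",".join(f"{v:.6g}" for v in ordination.eigenvalues[:10])
    write_result_table(coords, outdir / "ordination.tsv", meta_info)

    perm = permanova(dist, meta, n_perm=cfg.n_perm, seed=cfg.seed)
    info = dict(cfg.provenance())
    info["n_permutations"] = perm.n_permutations
    info["seed"] = cfg.seed
    info["permutation_scheme"] = perm.permutation_scheme
    write_result_table(perm.table, outdir / "permanova.tsv", info)

    counts_cols = []
    for table, m in studies:
        h = table.values.apply(shannon, axis=0)
        counts_cols.append(pd.DataFrame({
            "sample_id": h.index, "shannon": h.to_numpy(),
            "study_id": m.indexed().loc[h.index, "study_id"].to_numpy(),
            "timepoint_months": m.indexed().loc[h.index, "timepoint_months"].to_numpy(),
        }))
    shannon_df = pd.concat(counts_cols, ignore_index=True)
    write_result_table(shannon_df, outdir / "shannon.tsv", cfg.provenance())
    return perm, ordination, shannon_df


def stage_transfer(studies, cfg: RunConfig, outdir: Path) -> pd.DataFrame:
    results = transfer_matrix(studies, model_type=cfg.model, seed=cfg.seed,
                              k=cfg.k, repeats=cfg.repeats)
    results += loso(studies, model_type=cfg.model, seed=cfg.seed,
                    k=cfg.k, repeats=cfg.repeats)
    df = pd.DataFrame(
        [(r.train_study, r.test_study, r.mode, r.model_type, r.auroc) for r in results],
        columns=TRANSFER_COLUMNS,
    )
    info = dict(cfg.provenance())
    info["seed"] = cfg.seed
    write_result_table(df, outdir / "transfer.tsv", info)
    return df


def run_pipeline(cfg: RunConfig, outdir) -> dict:
    """Run every stage and write a manifest; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    studies = load_studies(cfg, outdir)
    stage = "scan"
    try:
        signatures = stage_scan(studies, cfg, outdir)
        stage = "concordance"
        tidy, summary = stage_concord(signatures, cfg, outdir)
        stage = "community"
        perm, ordination, shannon_df = stage_community(studies, cfg, outdir)
        stage = "transfer"
        transfer_df = stage_transfer(studies, cfg, outdir)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config_hash": cfg.config_hash(),
        "cohortsig_version": __version__,
        "seed": cfg.seed,
        "n_studies": len(studies),
        "rows": {
            "signatures": int(len(signatures)),
            "concordance_pairs": int(len(tidy)),
            "permanova_terms": int(len(perm.table)),
            "ordination_samples": int(len(ordination.sample_ids)),
            "shannon_samples": int(len(shannon_df)),
            "transfer_results": int(len(transfer_df)),
        },
        "concordance_summary": summary,
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
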