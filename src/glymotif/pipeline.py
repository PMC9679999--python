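"""End-to-end pipeline: scans → Zs matrices → rules → clusters → reports.

All stage parameters live in one :class:`PipelineConfig`; the serialized
config is embedded in the output manifest for provenance, and every run writes
a QC log listing each exclusion with its triggering rule.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from .arrays import ProcessingConfig, QCLog, process_arrays
from .cluster import cluster_profiles, heatmap_export
from .features import FeatureMatrix, build_feature_matrix, default_catalog, load_catalog
from .glycans import parse_condensed
from .report import build_report, render_report
from .rules import MiningConfig, RuleSet, mine_ruleset

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    processing: ProcessingConfig = field(default_factory=ProcessingConfig)
    mining: MiningConfig = field(default_factory=MiningConfig)
    catalog_path: str | None = None   # None = built-in curated catalog
    contrast_q: float = 0.05
    cluster_glycans: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        if "processing" in raw:
            cfg.processing = ProcessingConfig(**raw["processing"])
        if "mining" in raw:
            cfg.mining = MiningConfig(**raw["mining"])
        for key in ("catalog_path", "contrast_q", "cluster_glycans", "seed"):
            if key in raw:
                setattr(cfg, key, raw[key])
        return cfg


@dataclass
class PipelineResult:
    zs: pd.DataFrame
    processed: pd.DataFrame
    labels: pd.DataFrame
    features: FeatureMatrix
    rulesets: dict[str, RuleSet]
    reports: dict[str, tuple[str, str]]   # lectin -> (json, text)
    qc: QCLog
    manifest: dict


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    scans_df: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Execute the fixed stage order on a long-format scan table.

    Stages: spot averaging and Z-scoring with all exclusion filters → Stouffer
    combination and flagging → background subtraction → binder calls → glycan
    featurization → per-lectin rule mining → clustering → annotation reports.
    When ``outdir`` is given, matrices (CSV), rules/reports/QC (JSON), the
    lectin dendrogram (Newick) and a manifest with file hashes and the full
    config are written there.
    """
    config = config or PipelineConfig()
    config.mining.seed = config.seed
    matrix, qc = process_arrays(scans_df, metadata, config.processing)

    structures = (scans_df.drop_duplicates("glycan_id")
                  .set_index("glycan_id")["structure"])
    glycan_ids = list(matrix.labels.index)
    library = [parse_condensed(structures[gid]) for gid in glycan_ids]
    catalog = (load_catalog(config.catalog_path) if config.catalog_path
               else default_catalog())
    features = build_feature_matrix(library, catalog, glycan_ids)

    rulesets: dict[str, RuleSet] = {}
    reports: dict[str, tuple[str, str]] = {}
    for lectin_id in matrix.labels.columns:
        labels = matrix.labels[lectin_id]
        try:
            rs = mine_ruleset(features, labels, config.mining, lectin_id=lectin_id)
        except ValueError as exc:
            rs = RuleSet(lectin_id=lectin_id, stop_reason=str(exc))
            qc.record("mining_skipped", lectin_id, "insufficient_class_balance",
                      detail=str(exc))
        rulesets[lectin_id] = rs
        rep = build_report(lectin_id, rs, features, labels, config.contrast_q)
        reports[lectin_id] = render_report(rep)

    lectin_clust = cluster_profiles(matrix.processed, axis="lectins")
    glycan_clust = (cluster_profiles(matrix.processed, axis="glycans")
                    if config.cluster_glycans and matrix.processed.shape[0] > 2
                    else None)
    ordered, binary = heatmap_export(matrix.processed, lectin_clust, glycan_clust,
                                     threshold=config.processing.z_threshold)

    manifest = {"config": config.to_dict(), "outputs": {}}
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        matrix.zs.to_csv(out / "zs.csv", index_label="glycan_id")
        matrix.processed.to_csv(out / "processed.csv", index_label="glycan_id")
        matrix.labels.to_csv(out / "labels.csv", index_label="glycan_id")
        ordered.to_csv(out / "heatmap_ordered.csv", index_label="glycan_id")
        binary.to_csv(out / "heatmap_binary.csv", index_label="glycan_id")
        features.to_csv(str(out / "features.csv"))
        (out / "dendrogram_lectins.nwk").write_text(lectin_clust.to_newick() + "\n")
        if glycan_clust is not None:
            (out / "dendrogram_glycans.nwk").write_text(glycan_clust.to_newick() + "\n")
        rules_blob = {lid: rs.to_dict() for lid, rs in rulesets.items()}
        (out / "rules.json").write_text(json.dumps(rules_blob, indent=2))
        reports_dir = out / "reports"
        reports_dir.mkdir(exist_ok=True)
        for lid, (js, txt) in reports.items():
            (reports_dir / f"{lid}.json").write_text(js)
            (reports_dir / f"{lid}.txt").write_text(txt)
        qc.to_json(str(out / "qc.json"))
        for f in sorted(out.rglob("*")):
            if f.is_file() and f.name != "manifest.json":
                manifest["outputs"][str(f.relative_to(out))] = _sha256(f)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return PipelineResult(zs=matrix.zs, processed=matrix.processed,
                          labels=matrix.labels, features=features,
                          rulesets=rulesets, reports=reports, qc=qc,
                          manifest=manifest)
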