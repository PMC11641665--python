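"""End-to-end orchestration: simulate/load -> partition -> discover ->
score -> classify -> survive, with deterministic per-stage seeding.

A single global seed fans out to per-stage child seeds via a stage-name CRC
hash, so each stage is independently reproducible; rerunning with the same
config and seed produces byte-identical report files. Every run writes a
manifest with input hashes, a config echo and the artifact list.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .activity import (
    DEFAULT_ALPHA,
    activity_matrix,
    select_significant,
    significance_table,
)
from .classify import KnnConfig, nested_cv
from .discovery import (
    discovery_report,
    gene_statistics,
    merge_overlapping,
    rank_subnetworks,
    score_subnetworks,
)
from .io_formats import (
    ExpressionDataset,
    SubnetmarkError,
    read_expression,
    read_network,
    restrict_to_common_genes,
    write_expression,
    write_network,
    write_report,
)
from .partition import PartitionConfig, partition
from .survival import survival_report
from .synthetic import SimulationConfig, simulate_all

logger = logging.getLogger("subnetmark")

__all__ = ["PipelineConfig", "run_pipeline", "child_seed"]


@dataclass(frozen=True)
class PipelineConfig:
    """Every constant of an analysis run in one place.

    Exactly one of ``simulation`` or the (expression, annotation, network)
    paths must be provided.
    """

    simulation: Optional[SimulationConfig] = None
    expression_path: Optional[str] = None
    annotation_path: Optional[str] = None
    network_path: Optional[str] = None
    label_column: str = "class"
    min_confidence: float = 700.0
    partition: PartitionConfig = field(default_factory=PartitionConfig)
    jaccard_threshold: float = 0.5
    statistic: str = "iqr"
    alpha: float = DEFAULT_ALPHA
    gene_scope: str = "all_genes"
    knn: KnnConfig = field(default_factory=KnnConfig)
    risk_quantile: float = 0.5
    outdir: str = "subnetmark_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        sim_mode = self.simulation is not None
        file_mode = self.expression_path is not None
        if sim_mode == file_mode:
            raise SubnetmarkError(
                "provide exactly one of simulation config or input paths"
            )
        if file_mode and self.network_path is None:
            raise SubnetmarkError("file mode needs a network_path")
        if not (0.0 < self.alpha <= 1.0):
            raise SubnetmarkError("alpha must be in (0, 1]")


def child_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed: (seed * 1000003 + crc32(stage)) mod 2^31."""
    return (seed * 1000003 + zlib.crc32(stage.encode())) % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _build_fold_features(dataset, ranked, gene_scope, statistic):
    """Feature builder for nested CV: re-estimate gene directions on the
    outer-training samples only, then score all samples with those frozen
    directions — the anti-leakage contract."""
    from .activity import activity_score

    def builder(train_idx: np.ndarray, test_idx: np.ndarray):
        ds_train = dataset.subset_samples(list(train_idx))
        stats = gene_statistics(ds_train, statistic=statistic)
        cols = []
        for s in ranked:
            refit = dataclasses.replace(
                s,
                directions={
                    g: stats[g].direction
                    for g in sorted(s.gene_set)
                    if g in stats and np.isfinite(stats[g].t_iqr)
                },
                representatives=[
                    stats[r.gene_id] for r in s.representatives if r.gene_id in stats
                ],
            )
            cols.append(activity_score(refit, dataset, gene_scope))
        feats = np.column_stack(cols)
        return feats[train_idx], feats[test_idx]

    return builder


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the manifest (also written to disk).

    Stage failures propagate as :class:`SubnetmarkError` naming the stage;
    the manifest is only written after all stages succeed, so a partial
    output tree is recognizable by its missing manifest.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []
    inputs: dict[str, str] = {}
    stage = "setup"
    try:
        # -- inputs --------------------------------------------------------
        stage = "simulate" if config.simulation is not None else "load"
        if config.simulation is not None:
            sim = replace(config.simulation, seed=child_seed(config.seed, "simulate"))
            logger.info("simulating: %s", sim)
            dataset, network, truth = simulate_all(sim)
            write_expression(dataset, outdir / "expression.tsv",
                             outdir / "annotation.tsv", config.label_column)
            write_network(network, outdir / "network.tsv")
            write_report(truth.to_dict(), outdir / "truth.json")
            artifacts.append("truth.json")
            for name in ("expression.tsv", "annotation.tsv", "network.tsv"):
                inputs[name] = _sha256(outdir / name)
        else:
            dataset = read_expression(config.expression_path,
                                      config.annotation_path, config.label_column)
            network = read_network(config.network_path, config.min_confidence)
            for key in ("expression_path", "annotation_path", "network_path"):
                p = getattr(config, key)
                if p:
                    inputs[key] = _sha256(Path(p))
        dataset, network = restrict_to_common_genes(dataset, network)

        # -- partition -----------------------------------------------------
        stage = "partition"
        logger.info("partitioning (min_size=%d, max_size=%d)",
                    config.partition.min_size, config.partition.max_size)
        candidates = partition(network, config.partition)
        with open(outdir / "membership.tsv", "w") as fh:
            fh.write("subnetwork_id\tgene_id\n")
            for c in candidates:
                for g in sorted(c.gene_set):
                    fh.write(f"{c.id}\t{g}\n")
        artifacts.append("membership.tsv")

        # -- discovery -----------------------------------------------------
        stage = "discover"
        logger.info("scoring %d candidates (statistic=%s, top-5 representatives)",
                    len(candidates), config.statistic)
        scored = score_subnetworks(candidates, dataset, network, config.statistic)
        scored = merge_overlapping(scored, dataset, network,
                                   config.jaccard_threshold, config.statistic)
        ranked = rank_subnetworks(scored)
        write_report(discovery_report(ranked), outdir / "discovery.json")
        artifacts.append("discovery.json")

        # -- activity + significance ----------------------------------------
        stage = "score"
        activity = activity_matrix(ranked, dataset, config.gene_scope)
        write_report(activity, outdir / "activity.tsv")
        artifacts.append("activity.tsv")
        records = significance_table(activity, dataset, config.alpha)
        selected = select_significant(records, config.alpha)
        logger.info("significance: %d/%d subnetworks at BH-adjusted p < %g",
                    len(selected), len(records), config.alpha)
        write_report({"alpha": config.alpha, "records": records},
                     outdir / "significance.json")
        artifacts.append("significance.json")

        feature_ids = [r.subnetwork_id for r in selected]
        if not feature_ids:
            feature_ids = [s.id for s in ranked[:4]]
            logger.info("no significant subnetworks; falling back to top-%d ranked",
                        len(feature_ids))
        feature_subnets = [s for s in ranked if s.id in feature_ids]

        # -- classification --------------------------------------------------
        stage = "classify"
        knn = replace(config.knn, seed=child_seed(config.seed, "classify"))
        logger.info("nested CV: %d outer / %d inner folds, city-block KNN "
                    "(k grid %s)", knn.n_outer, knn.n_inner, knn.k_grid)
        builder = _build_fold_features(dataset, feature_subnets,
                                       config.gene_scope, config.statistic)
        feats = np.column_stack([activity.row(i) for i in feature_ids])
        report = nested_cv(feats, dataset.class_labels, knn, feature_builder=builder)
        write_report(report, outdir / "classification.json")
        artifacts.append("classification.json")

        # -- survival --------------------------------------------------------
        stage = "survive"
        if dataset.clinical is not None and not dataset.clinical.empty:
            orient = {r.subnetwork_id: r.welch_t for r in records}
            surv = survival_report(activity, dataset, feature_ids, orient,
                                   quantile=config.risk_quantile)
            write_report(surv, outdir / "survival.json")
            artifacts.append("survival.json")
        else:
            logger.info("no clinical records; survival stage skipped")

    except SubnetmarkError as exc:
        raise SubnetmarkError(f"stage {stage!r} failed: {exc}") from exc

    config_echo = dataclasses.asdict(config)
    config_echo.pop("outdir")  # implied by the manifest's location
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {
            s: child_seed(config.seed, s) for s in ("simulate", "classify")
        },
        "config": config_echo,
        "inputs": inputs,
        "artifacts": sorted(artifacts),
    }
    manifest["artifacts_sha256"] = {
        a: _sha256(outdir / a) for a in sorted(artifacts)
    }
    write_report(manifest, outdir / "manifest.json")
    return manifest
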