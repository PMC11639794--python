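"""End-to-end orchestration: filter -> specificity -> structure -> clustering
-> network -> enrichment -> report, with a manifest for provenance.

All randomness flows from one root seed; deterministic stages are
bit-identical across reruns with the same config and inputs.  Every emitted
file is listed in ``manifest.json`` with a SHA-256 checksum together with
the config hash, seed and package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import ExpressionMatrix, filter_min_tpm, read_expression_matrix, write_expression_matrix
from . import specificity as spec_mod
from .structure import hclust_samples, pca, pearson_matrix
from .clustering import cluster_hkg_profiles, optimal_k
from .network import build_network, gene_module_statistics, hub_genes, module_trait_correlation, tissue_indicator_traits
from .enrichment import enrich, read_gmt

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

STAGES = ("filter", "specificity", "classify", "structure", "cluster", "network", "report")


@dataclass
class PipelineConfig:
    """Thresholds and knobs of the full pipeline (defaults as documented)."""

    matrix: str = ""
    annotation_gmt: str | None = None
    out_dir: str = "atlas_out"
    tpm_min: float = 1.0
    tsg_high: float = 0.8
    hkg_low: float = 0.2
    counts_threshold: float = 1.0
    k_range: tuple[int, int] = (2, 8)
    seed: int = 0
    gap_B: int = 50
    beta: int | None = None  # None = automatic by scale-free fit
    target_r2: float = 0.8
    min_module_size: int = 30
    hub_fraction: float = 0.05
    fdr_max: float = 0.05
    min_overlap: int = 3
    edge_min_tom: float = 0.1

    def __post_init__(self) -> None:
        if not 0 <= self.hkg_low < self.tsg_high <= 1:
            raise ValueError("need 0 <= hkg_low < tsg_high <= 1")
        if self.tpm_min < 0 or self.counts_threshold <= 0:
            raise ValueError("tpm_min must be >= 0 and counts_threshold > 0")
        if not 0 < self.hub_fraction <= 1:
            raise ValueError("hub_fraction must be in (0, 1]")
        if not 0 < self.fdr_max <= 1:
            raise ValueError("fdr_max must be in (0, 1]")
        lo, hi = self.k_range
        if not 1 <= lo < hi:
            raise ValueError("k_range must be an increasing pair with lo >= 1")
        if self.beta is not None and self.beta < 1:
            raise ValueError("beta must be >= 1 (or None for automatic)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "k_range" in raw:
            raw["k_range"] = tuple(raw["k_range"])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig, matrix: ExpressionMatrix | None = None) -> dict:
    """Execute every stage in order and write a manifest.

    ``matrix`` may be passed directly (e.g. a synthetic atlas) instead of
    reading ``cfg.matrix`` from disk.  Any stage failure aborts with the
    stage name and cause; files written so far are retained.  Returns the
    manifest dictionary.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, list[str]] = {}
    summary: dict = {}

    def emit(stage: str, name: str, df: pd.DataFrame, **kwargs) -> None:
        path = out / name
        df.to_csv(path, sep="\t", **kwargs)
        files.setdefault(stage, []).append(name)

    stage = "filter"
    try:
        if matrix is None:
            matrix = read_expression_matrix(cfg.matrix)
        filtered = filter_min_tpm(matrix, cfg.tpm_min)
        logger.info("filter: %d of %d genes reach TPM %g", filtered.n_genes, matrix.n_genes, cfg.tpm_min)
        write_expression_matrix(filtered, out / "filtered_matrix.tsv")
        files[stage] = ["filtered_matrix.tsv"]
        summary["genes_in"] = matrix.n_genes
        summary["genes_after_filter"] = filtered.n_genes

        stage = "specificity"
        scores = spec_mod.score_matrix(filtered, threshold=cfg.counts_threshold)
        cv = pd.Series(
            [spec_mod.coefficient_of_variation(row) for row in filtered.values],
            index=filtered.data.index, name="cv",
        )
        bands = spec_mod.variability_bands(cv)
        spec_table = scores.assign(cv=cv, variability_band=bands)
        emit(stage, "specificity_scores.tsv", spec_table, index_label="gene_id")

        stage = "classify"
        classes = spec_mod.classify(scores, high=cfg.tsg_high, low=cfg.hkg_low)
        tsg_ids = classes.index[classes["label"] == spec_mod.TSG]
        tissue_of = spec_mod.assign_tsg_tissue(filtered, tsg_ids)
        classes = classes.assign(tsg_tissue=tissue_of.reindex(classes.index))
        emit(stage, "classification.tsv", classes, index_label="gene_id")
        hkg_ids = list(classes.index[classes["label"] == spec_mod.HKG])
        summary["n_hkg"] = len(hkg_ids)
        summary["n_tsg"] = int((classes["label"] == spec_mod.TSG).sum())
        summary["tsg_per_tissue"] = tissue_of.value_counts().to_dict()

        stage = "structure"
        corr = pearson_matrix(filtered)
        emit(stage, "tissue_correlation.tsv", corr, index_label="tissue")
        pca_res = pca(filtered)
        emit(stage, "pca_scores.tsv", pca_res.scores, index_label="tissue")
        emit(
            stage, "pca_variance.tsv",
            pd.DataFrame({"variance_percent": pca_res.variance_explained},
                         index=pca_res.scores.columns),
            index_label="component",
        )
        (out / "tissue_dendrogram.nwk").write_text(hclust_samples(corr).to_newick() + "\n")
        files[stage].append("tissue_dendrogram.nwk")

        stage = "cluster"
        if len(hkg_ids) >= cfg.k_range[1] + 1:
            hkg_log = np.log2(filtered.subset(hkg_ids).values + 1.0)
            sd = hkg_log.std(axis=1, keepdims=True)
            z = (hkg_log - hkg_log.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)
            report = optimal_k(
                z, k_range=range(cfg.k_range[0], cfg.k_range[1] + 1),
                seed=cfg.seed, gap_B=cfg.gap_B,
            )
            emit(stage, "optimal_k_report.tsv", report.table)
            res, csum = cluster_hkg_profiles(filtered, hkg_ids, report.consensus_k, seed=cfg.seed)
            emit(
                stage, "hkg_clusters.tsv",
                pd.DataFrame({"cluster": res.assignments}, index=hkg_ids),
                index_label="gene_id",
            )
            emit(stage, "hkg_cluster_summary.tsv", csum)
            means = (
                pd.DataFrame(hkg_log, index=hkg_ids, columns=filtered.tissue_labels)
                .groupby(pd.Series(res.assignments, index=hkg_ids)).mean()
            )
            emit(stage, "cluster_tissue_means.tsv", means, index_label="cluster")
            summary["consensus_k"] = report.consensus_k
            summary["chosen_k"] = report.chosen_k
        else:
            logger.warning("cluster: too few HKGs (%d); stage records an empty table", len(hkg_ids))
            emit(stage, "hkg_clusters.tsv", pd.DataFrame(columns=["cluster"]), index_label="gene_id")

        stage = "network"
        net_ids = hkg_ids if len(hkg_ids) >= 3 else list(filtered.data.index)
        log_expr = pd.DataFrame(
            np.log2(filtered.subset(net_ids).values + 1.0),
            index=net_ids, columns=filtered.tissue_labels,
        )
        net = build_network(
            log_expr, beta=cfg.beta, target_r2=cfg.target_r2,
            min_module_size=cfg.min_module_size,
        )
        emit(stage, "soft_threshold.tsv", net.soft_threshold.table)
        emit(stage, "module_labels.tsv", net.labels.to_frame(), index_label="gene_id")
        emit(stage, "module_eigengenes.tsv", net.eigengenes, index_label="module")
        traits = tissue_indicator_traits(filtered.tissue_labels)
        mt_r, mt_p = module_trait_correlation(net.eigengenes, traits)
        emit(stage, "module_trait_r.tsv", mt_r, index_label="module")
        emit(stage, "module_trait_p.tsv", mt_p, index_label="module")
        gstats = gene_module_statistics(log_expr, net.eigengenes, net.labels, traits)
        hub = hub_genes(net.adjacency, net.labels, fraction=cfg.hub_fraction)
        emit(
            stage, "kim_kme.tsv",
            gstats["kme"].add_prefix("kME_").assign(kim=hub.kim),
            index_label="gene_id",
        )
        emit(stage, "gs_mm.tsv", gstats["gs_mm"])
        emit(
            stage, "hub_genes.tsv",
            pd.DataFrame(
                [(mod, g) for mod, genes in hub.hubs.items() for g in genes],
                columns=["module", "gene_id"],
            ),
            index=False,
        )
        tom = net.tom.to_numpy()
        iu = np.triu_indices_from(tom, k=1)
        keep = tom[iu] >= cfg.edge_min_tom
        edges = pd.DataFrame(
            {
                "gene1": net.tom.index.to_numpy()[iu[0][keep]],
                "gene2": net.tom.index.to_numpy()[iu[1][keep]],
                "tom": tom[iu][keep],
            }
        )
        emit(stage, "network_edges.tsv", edges, index=False)
        summary["beta"] = net.beta
        summary["module_sizes"] = {str(k): int(v) for k, v in net.module_sizes.items()}
        summary["hub_counts"] = hub.counts()

        if cfg.annotation_gmt:
            stage = "enrichment"
            ann = read_gmt(cfg.annotation_gmt)
            universe = set(filtered.data.index) & set().union(*ann.genes.values())
            gene_sets = {"HKG": set(hkg_ids) & universe, "TSG": set(tsg_ids) & universe}
            for mod in net.labels.unique():
                gene_sets[f"module_{mod}"] = (
                    set(net.labels.index[net.labels == mod]) & universe
                )
            for name, genes in gene_sets.items():
                if not genes:
                    continue
                table = enrich(genes, universe, ann, fdr_max=cfg.fdr_max,
                               min_overlap=cfg.min_overlap)
                emit(stage, f"enrichment_{name}.tsv", table, index=False)

        stage = "report"
        manifest = {
            "version": __version__,
            "seed": cfg.seed,
            "config_hash": cfg.config_hash(),
            "config": asdict(cfg),
            "stages": {
                s: {
                    "files": {
                        f: _sha256(out / f) for f in files.get(s, [])
                    }
                }
                for s in files
            },
            "summary": summary,
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=1, default=str))
        files[stage] = ["summary.json"]
        manifest["stages"]["report"] = {
            "files": {"summary.json": _sha256(out / "summary.json")}
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        return manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
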