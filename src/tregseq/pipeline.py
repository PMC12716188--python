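"""End-to-end stage orchestration with run configuration and logging.

Stage order for single-cell analysis: QC -> normalize -> HVG -> PCA ->
batch-center -> kNN graph -> Leiden -> FOXP3-cluster calling ->
marker ranking.  All randomness flows from the single run seed;
stage-local seeds are derived deterministically from it.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bulkde, cluster, io, markers, qc, qpcr

__all__ = ["RunConfig", "RunLog", "run_sc_pipeline", "run_bulk_pipeline", "run_qpcr"]


@dataclass
class RunConfig:
    """Flat configuration for all pipeline stages."""

    seed: int = 0
    # QC
    min_genes: int = 200
    max_genes: int = 4000
    max_counts: int = 15000
    max_mito_ribo_frac: float = 0.20
    min_cells: int = 3
    # clustering
    scale_target: float | None = None
    n_hvg: int = 500
    n_pcs: int = 30
    k_neighbors: int = 15
    resolution: float = 1.5
    # marker / FOXP3 calling
    foxp3_gene: str = "FOXP3"
    pct_threshold: float = 0.10
    p_threshold: float = 0.05
    top_n_markers: int = 25
    # bulk
    padj_cutoff: float = 0.05

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        if self.n_hvg < 1 or self.n_pcs < 1 or self.k_neighbors < 1:
            raise ValueError("n_hvg, n_pcs and k_neighbors must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def qc_thresholds(self) -> qc.QCThresholds:
        return qc.QCThresholds(
            self.min_genes,
            self.max_genes,
            self.max_counts,
            self.max_mito_ribo_frac,
            self.min_cells,
        )

    def foxp3_config(self) -> markers.FoxP3CallConfig:
        return markers.FoxP3CallConfig(
            self.foxp3_gene, self.pct_threshold, self.p_threshold
        )


@dataclass
class RunLog:
    """Machine-readable record of every data-mutating stage."""

    stages: list = field(default_factory=list)

    def record(self, stage: str, **info) -> None:
        self.stages.append({"stage": stage, "time": time.time(), **info})

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"stages": self.stages}, fh, indent=2, default=str)


def _write_tsv(df: pd.DataFrame, path, **kw) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g", **kw)


def run_sc_pipeline(cm: qc.CountMatrix, cfg: RunConfig, outdir) -> dict:
    """QC, cluster and marker-score a count matrix; write all artifacts.

    Returns a dict with the in-memory stage products (filtered matrix,
    cluster assignment, FOXP3 calls, marker tables).  Re-running with
    the same config and input reproduces identical tables.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = RunLog()
    log.record("input", n_cells=cm.n_cells, n_genes=cm.n_genes, seed=cfg.seed)

    flagged = qc.flag_mito_ribo(cm.gene_ids)
    stats = qc.compute_cell_qc(cm, flagged)
    thresholds = cfg.qc_thresholds()
    filtered, cell_mask = qc.filter_cells(cm, stats, thresholds)
    _write_tsv(qc.qc_report(stats, thresholds), outdir / "qc_report.tsv")
    log.record(
        "filter_cells",
        kept=int(cell_mask.sum()),
        removed=int((~cell_mask).sum()),
        thresholds=asdict(thresholds),
    )
    filtered, gene_mask = qc.filter_genes(filtered, thresholds.min_cells)
    log.record("filter_genes", kept=int(gene_mask.sum()), removed=int((~gene_mask).sum()))

    nm = cluster.normalize_log(filtered, cfg.scale_target)
    hvg_idx = cluster.select_hvg(nm, min(cfg.n_hvg, nm.n_genes))
    emb = cluster.pca_embed(nm.values[:, hvg_idx], min(cfg.n_pcs, len(hvg_idx)))
    emb = cluster.center_batches(emb, filtered.batch)
    graph = cluster.build_knn_graph(emb, cfg.k_neighbors)
    ca = cluster.detect_communities(graph, cfg.resolution, seed=cfg.seed)
    log.record(
        "cluster",
        n_hvg=len(hvg_idx),
        n_pcs=emb.n_components,
        k=cfg.k_neighbors,
        resolution=cfg.resolution,
        n_clusters=ca.n_clusters,
    )
    _write_tsv(
        pd.DataFrame({"barcode": filtered.cell_ids, "cluster": ca.labels}),
        outdir / "clusters.tsv",
        index=False,
    )
    _write_tsv(
        pd.DataFrame(
            emb.coords,
            index=pd.Index(filtered.cell_ids, name="barcode"),
            columns=[f"PC{i + 1}" for i in range(emb.n_components)],
        ),
        outdir / "embedding.tsv",
    )

    called, evidence = markers.identify_foxp3_clusters(
        nm, filtered, ca, cfg.foxp3_config()
    )
    _write_tsv(evidence, outdir / "foxp3_clusters.tsv")
    log.record("identify_foxp3", called=[int(c) for c in called])

    marker_tables = {}
    dot_genes: list = []
    for c in called:
        tab = markers.rank_markers(
            nm, filtered, ca, c, top_n=cfg.top_n_markers, p_threshold=cfg.p_threshold
        )
        marker_tables[c] = tab
        _write_tsv(tab, outdir / f"markers_cluster{c}.tsv")
        dot_genes.extend(g for g in tab.index[:10] if g not in dot_genes)
    if dot_genes:
        stats_tab = markers.cluster_gene_stats(nm, filtered, ca)
        dot = pd.concat(
            {
                "mean_expr": stats_tab.mean_expr[dot_genes],
                "pct_expressing": stats_tab.pct_expressing[dot_genes],
            },
            axis=1,
        )
        _write_tsv(dot, outdir / "dotplot_table.tsv")
    log.write(outdir / "run_log.json")
    return {
        "filtered": filtered,
        "normalized": nm,
        "embedding": emb,
        "clusters": ca,
        "foxp3_clusters": called,
        "foxp3_evidence": evidence,
        "marker_tables": marker_tables,
    }


def run_bulk_pipeline(counts: pd.DataFrame, meta: pd.DataFrame, cfg: RunConfig, outdir) -> bulkde.NBDEResults:
    """NB differential expression over the CD25 design; write artifacts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = RunLog()
    missing = [s for s in counts.columns if s not in meta.index]
    extra = [s for s in meta.index if s not in counts.columns]
    if missing or extra:
        raise ValueError(
            f"counts/metadata sample mismatch: missing from metadata {missing}, "
            f"unmatched metadata rows {extra}"
        )
    model = bulkde.NegativeBinomialDE(counts, meta)
    res = model.fit()
    log.record(
        "fit",
        n_genes=counts.shape[0],
        n_samples=counts.shape[1],
        padj_cutoff=cfg.padj_cutoff,
    )
    _write_tsv(res.size_factors.to_frame(), outdir / "size_factors.tsv")
    for name, tab in res.tables.items():
        _write_tsv(tab, outdir / f"de_{name}.tsv")
    _write_tsv(res.zscore_matrix(), outdir / "zscore_matrix.tsv")
    venn = {
        direction: res.venn(cfg.padj_cutoff, direction)
        for direction in ("up", "down")
    }
    with open(outdir / "venn.json", "w") as fh:
        json.dump(venn, fh, indent=2, sort_keys=True)
    log.write(outdir / "run_log.json")
    return res


def run_qpcr(table: pd.DataFrame, control_group: str, outdir) -> dict:
    """dCT/ddCT fold changes and ANOVA + Tukey comparisons; write artifacts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if table.groupby("group").size().min() == 0 or table.empty:
        raise ValueError("qPCR table has an empty group")
    per_sample, summary = qpcr.ddct_fold_change(table, control_group)
    f_stat, p_omni, pairwise = qpcr.anova_tukey(
        per_sample["fold"].to_numpy(), per_sample["group"].to_numpy()
    )
    _write_tsv(per_sample, outdir / "fold_changes.tsv", index=False)
    _write_tsv(summary, outdir / "group_summary.tsv", index=False)
    _write_tsv(pairwise, outdir / "comparisons.tsv", index=False)
    with open(outdir / "anova.json", "w") as fh:
        json.dump({"f_stat": f_stat, "p_omnibus": p_omni}, fh, indent=2)
    return {
        "per_sample": per_sample,
        "summary": summary,
        "f_stat": f_stat,
        "p_omnibus": p_omni,
        "pairwise": pairwise,
    }
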