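"""Cell- and gene-level quality control for single-cell count matrices.

Filters follow the conventions of droplet scRNA-seq preprocessing:
cells are kept when they show a plausible number of detected genes
(``min_genes <= n <= max_genes``), a bounded library size
(``total_counts <= max_counts``) and a bounded fraction of counts from
mitochondrial/ribosomal genes; genes are kept when detected in at least
``min_cells`` cells.  All thresholds are inclusive on the "keep" side.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "QCThresholds",
    "flag_mito_ribo",
    "compute_cell_qc",
    "filter_cells",
    "filter_genes",
    "qc_report",
]

#: gene-name prefixes treated as mitochondrial/ribosomal
MITO_RIBO_PREFIXES = ("MT-", "RPL", "RPS")


@dataclass
class CountMatrix:
    """Sparse cells x genes integer count matrix with annotations.

    Parameters
    ----------
    counts
        Non-negative integer matrix, cells in rows, genes in columns.
        Stored as CSR.
    cell_ids
        Unique cell barcodes, one per row.
    gene_ids
        Gene identifiers, one per column.
    batch
        Per-cell batch label.  Defaults to a single batch ``"0"``.
    """

    counts: sp.spmatrix
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    batch: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.batch is None:
            self.batch = np.zeros(self.counts.shape[0], dtype=object)
            self.batch[:] = "0"
        else:
            self.batch = np.asarray(self.batch, dtype=object)
        n_cells, n_genes = self.counts.shape
        if len(self.cell_ids) != n_cells:
            raise ValueError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix rows"
            )
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix columns"
            )
        if len(self.batch) != n_cells:
            raise ValueError("batch labels must align with cells")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("cell barcodes must be unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("count matrix contains negative entries")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset(self, cell_mask=None, gene_mask=None) -> "CountMatrix":
        """Return a new matrix restricted to masked cells/genes, order preserved."""
        m = self.counts
        cells, genes, batch = self.cell_ids, self.gene_ids, self.batch
        if cell_mask is not None:
            cell_mask = np.asarray(cell_mask, dtype=bool)
            m = m[cell_mask]
            cells = cells[cell_mask]
            batch = batch[cell_mask]
        if gene_mask is not None:
            gene_mask = np.asarray(gene_mask, dtype=bool)
            m = m[:, gene_mask]
            genes = genes[gene_mask]
        return CountMatrix(m, cells, genes, batch)


@dataclass(frozen=True)
class QCThresholds:
    """Cell/gene filter thresholds; defaults are the pipeline defaults."""

    min_genes: int = 200
    max_genes: int = 4000
    max_counts: int = 15000
    max_mito_ribo_frac: float = 0.20
    min_cells: int = 3

    def __post_init__(self) -> None:
        if self.min_genes >= self.max_genes:
            raise ValueError("min_genes must be < max_genes")
        for name in ("min_genes", "max_counts", "max_mito_ribo_frac", "min_cells"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def flag_mito_ribo(gene_ids, prefixes=MITO_RIBO_PREFIXES) -> set:
    """Genes considered mitochondrial/ribosomal, by name prefix."""
    return {g for g in gene_ids if str(g).startswith(tuple(prefixes))}


def compute_cell_qc(m: CountMatrix, flagged_genes) -> pd.DataFrame:
    """Per-cell QC statistics.

    Returns a frame indexed by barcode with columns ``n_genes_detected``,
    ``total_counts`` and ``mito_ribo_frac`` (the fraction of a cell's
    counts that come from ``flagged_genes``; 0 for an all-zero cell).
    """
    flagged = set(flagged_genes)
    unknown = flagged - set(m.gene_ids)
    if unknown:
        raise ValueError(f"flagged gene(s) not in matrix: {sorted(map(str, unknown))}")
    counts = m.counts
    n_detected = np.asarray((counts > 0).sum(axis=1)).ravel()
    totals = np.asarray(counts.sum(axis=1)).ravel()
    flag_mask = np.fromiter((g in flagged for g in m.gene_ids), bool, m.n_genes)
    flagged_totals = np.asarray(counts[:, flag_mask].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore"):
        frac = np.where(totals > 0, flagged_totals / np.maximum(totals, 1), 0.0)
    return pd.DataFrame(
        {
            "n_genes_detected": n_detected.astype(int),
            "total_counts": totals.astype(int),
            "mito_ribo_frac": frac,
        },
        index=pd.Index(m.cell_ids, name="barcode"),
    )


def _cell_keep_mask(stats: pd.DataFrame, t: QCThresholds) -> np.ndarray:
    return (
        (stats["n_genes_detected"] >= t.min_genes)
        & (stats["n_genes_detected"] <= t.max_genes)
        & (stats["total_counts"] <= t.max_counts)
        & (stats["mito_ribo_frac"] <= t.max_mito_ribo_frac)
    ).to_numpy()


def failing_criterion(stats: pd.DataFrame, t: QCThresholds) -> pd.Series:
    """First violated criterion per cell ('' for passing cells)."""
    out = []
    for _, row in stats.iterrows():
        if row["n_genes_detected"] < t.min_genes:
            out.append("min_genes")
        elif row["n_genes_detected"] > t.max_genes:
            out.append("max_genes")
        elif row["total_counts"] > t.max_counts:
            out.append("max_counts")
        elif row["mito_ribo_frac"] > t.max_mito_ribo_frac:
            out.append("max_mito_ribo_frac")
        else:
            out.append("")
    return pd.Series(out, index=stats.index, name="failing_criterion")


def filter_cells(m: CountMatrix, stats: pd.DataFrame, t: QCThresholds):
    """Keep cells passing all thresholds (inclusive boundaries).

    Returns ``(filtered_matrix, keep_mask)``.  Raises if nothing survives,
    which almost always means the thresholds need review.
    """
    if len(stats) != m.n_cells:
        raise ValueError("stats not aligned to matrix")
    keep = _cell_keep_mask(stats, t)
    if not keep.any():
        raise ValueError(
            "no cells pass QC; review thresholds "
            f"(min_genes={t.min_genes}, max_genes={t.max_genes}, "
            f"max_counts={t.max_counts}, max_mito_ribo_frac={t.max_mito_ribo_frac})"
        )
    return m.subset(cell_mask=keep), keep


def filter_genes(m: CountMatrix, min_cells: int):
    """Keep genes detected (count > 0) in at least ``min_cells`` cells.

    Returns ``(filtered_matrix, keep_mask)``.
    """
    if min_cells < 0:
        raise ValueError("min_cells must be >= 0")
    n_cells_detected = np.asarray((m.counts > 0).sum(axis=0)).ravel()
    keep = n_cells_detected >= min_cells
    return m.subset(gene_mask=keep), keep


def qc_report(stats: pd.DataFrame, t: QCThresholds) -> pd.DataFrame:
    """TSV-ready per-cell report: stats, kept flag, failing criterion."""
    report = stats.copy()
    report["kept"] = _cell_keep_mask(stats, t)
    report["failing_criterion"] = failing_criterion(stats, t)
    return report
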