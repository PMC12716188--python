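"""Readers and writers for the on-disk formats.

Single-cell matrices travel as a CellRanger-style triplet directory:
``matrix.mtx`` (Matrix Market, genes x cells, 1-based, integer),
``features.tsv`` (one gene id per line) and ``barcodes.tsv``
(barcode, plus an optional second batch-label column).  Bulk counts
are a genes x samples CSV with a tab-separated sample metadata table;
qPCR tables are CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .qc import CountMatrix
from .simulate import SimTruth

__all__ = [
    "write_sc_dataset",
    "read_sc_dataset",
    "write_bulk_dataset",
    "read_bulk_dataset",
    "write_qpcr_dataset",
    "read_qpcr_dataset",
]


def write_sc_dataset(outdir, cm: CountMatrix, truth: SimTruth | None = None) -> Path:
    """Write a count matrix (and optional truth sidecars) as a triplet dir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat = sp.coo_matrix(cm.counts.T)  # genes x cells, CellRanger orientation
    mmwrite(outdir / "matrix.mtx", mat, field="integer")
    pd.DataFrame({"barcode": cm.cell_ids, "batch": cm.batch}).to_csv(
        outdir / "barcodes.tsv", sep="\t", header=False, index=False
    )
    pd.DataFrame({"gene": cm.gene_ids}).to_csv(
        outdir / "features.tsv", sep="\t", header=False, index=False
    )
    if truth is not None and truth.true_cluster_of_cell is not None:
        pd.DataFrame(
            {"barcode": cm.cell_ids, "true_cluster": truth.true_cluster_of_cell}
        ).to_csv(outdir / "true_clusters.tsv", sep="\t", index=False)
        rows = [
            {"cluster": c, "gene": g}
            for c, genes in sorted(truth.planted_markers.items())
            for g in sorted(genes)
        ]
        pd.DataFrame(rows, columns=["cluster", "gene"]).to_csv(
            outdir / "planted_markers.tsv", sep="\t", index=False
        )
    return outdir


def read_sc_dataset(indir) -> CountMatrix:
    """Read a triplet directory back into a :class:`CountMatrix`."""
    indir = Path(indir)
    mat = mmread(indir / "matrix.mtx").tocsr().T.tocsr()
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)
    features = pd.read_csv(indir / "features.tsv", sep="\t", header=None)
    batch = (
        barcodes[1].to_numpy(dtype=object) if barcodes.shape[1] > 1 else None
    )
    return CountMatrix(
        mat.astype(np.int64),
        barcodes[0].to_numpy(dtype=object),
        features[0].to_numpy(dtype=object),
        batch,
    )


def write_bulk_dataset(outdir, counts: pd.DataFrame, meta: pd.DataFrame) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts.to_csv(outdir / "counts.csv")
    meta.to_csv(outdir / "metadata.tsv", sep="\t")
    return outdir


def read_bulk_dataset(counts_csv, meta_tsv):
    counts = pd.read_csv(counts_csv, index_col=0)
    meta = pd.read_csv(meta_tsv, sep="\t", index_col=0)
    return counts, meta


def write_qpcr_dataset(path, table: pd.DataFrame) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


def read_qpcr_dataset(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    required = {"sample", "group", "ct_target", "ct_reference"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"qPCR CSV lacks column(s): {sorted(missing)}")
    return table
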