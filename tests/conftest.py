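"""Shared fixtures: small synthetic datasets reused across test modules."""

import numpy as np
import pytest

from tregseq import cluster as cl
from tregseq import qc
from tregseq.simulate import BulkSimConfig, ScSimConfig, simulate_bulk_dataset, simulate_sc_dataset

#: QC thresholds scaled to the small test matrices (the defaults assume
#: a 2,000-gene universe)
SMALL_QC = qc.QCThresholds(
    min_genes=10, max_genes=4000, max_counts=15000, max_mito_ribo_frac=0.5, min_cells=3
)


def small_sc_config(seed: int = 0, **overrides) -> ScSimConfig:
    defaults = dict(
        n_cells=800,
        n_genes=400,
        n_clusters=5,
        treg_cluster_fracs=(0.05, 0.04),
        signature_genes_per_cluster=20,
        seed=seed,
    )
    defaults.update(overrides)
    return ScSimConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_sc():
    """Small simulated single-cell dataset: (CountMatrix, SimTruth)."""
    return simulate_sc_dataset(small_sc_config(seed=0))


@pytest.fixture(scope="session")
def sc_processed(tiny_sc):
    """QC'd, normalized, embedded and clustered small dataset."""
    cm, truth = tiny_sc
    flagged = qc.flag_mito_ribo(cm.gene_ids)
    stats = qc.compute_cell_qc(cm, flagged)
    filtered, cell_mask = qc.filter_cells(cm, stats, SMALL_QC)
    filtered, _ = qc.filter_genes(filtered, SMALL_QC.min_cells)
    nm = cl.normalize_log(filtered)
    hvg = cl.select_hvg(nm, 200)
    emb = cl.center_batches(cl.pca_embed(nm.values[:, hvg], 20), filtered.batch)
    ca = cl.detect_communities(cl.build_knn_graph(emb, 15), 1.0, seed=0)
    return {
        "raw": filtered,
        "nm": nm,
        "emb": emb,
        "ca": ca,
        "truth_labels": truth.true_cluster_of_cell[cell_mask],
        "truth": truth,
    }


@pytest.fixture(scope="session")
def bulk_null():
    """Null 12-sample bulk dataset (no planted effects), alpha=0.1."""
    return simulate_bulk_dataset(BulkSimConfig(n_genes=400, dispersion=0.1, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
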