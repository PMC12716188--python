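"""Synthetic single-cell, bulk and qPCR data with recorded ground truth.

The generators emulate the statistical structure the downstream
analysis assumes:

* a single-cell count matrix of ~5,000 cells in a dozen clusters, two
  of them rare (~4.1% and ~3.0%) FOXP3+ regulatory T cell (Treg)
  clusters carrying a designated marker panel, with per-cell library
  size variation, per-gene-per-batch offsets, and mitochondrial/
  ribosomal genes recognizable by name prefix;
* a 12-sample bulk design (3 CD25 sorting groups x 4 birds, sex as a
  covariate) with planted log2 effects;
* qPCR cycle-threshold tables with group-level dCT shifts.

All counts are negative binomial with mean ``mu`` and dispersion
``alpha`` (variance ``mu + alpha mu^2``), drawn as a gamma-Poisson
mixture — the same parameterization the DE engine assumes.  Every
generator is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .qc import CountMatrix

__all__ = [
    "ScSimConfig",
    "BulkSimConfig",
    "SimTruth",
    "DEFAULT_TREG_PANELS",
    "simulate_sc_dataset",
    "simulate_bulk_dataset",
    "simulate_qpcr_dataset",
    "nb_counts",
]

#: default marker panels for the two planted Treg clusters: canonical
#: Treg-associated genes, 10 per cluster, elevated 8-fold
DEFAULT_TREG_PANELS = {
    0: (
        "CTLA4", "TNFRSF18", "IL2RA", "IKZF2", "TNFRSF4",
        "CCR8", "TGFB1", "IL10", "LAG3", "PDCD1",
    ),
    1: (
        "ICOS", "TNFRSF9", "ENTPD1", "NT5E", "IL2RB",
        "STAT5A", "FOXO1", "BATF", "TIGIT", "DUSP14",
    ),
}
DEFAULT_MARKER_FOLD = 8.0


def nb_counts(rng: np.random.Generator, mean, alpha: float):
    """NB(mu, alpha) draws via the gamma-Poisson mixture, any mean shape."""
    mean = np.asarray(mean, dtype=float)
    if alpha < 1e-12:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mean)
    return rng.poisson(lam)


@dataclass
class SimTruth:
    """Ground truth recorded by the generators for recovery tests."""

    true_cluster_of_cell: np.ndarray = None
    planted_markers: dict = field(default_factory=dict)
    true_lfc: dict = field(default_factory=dict)
    true_null_genes: set = field(default_factory=set)


# ---------------------------------------------------------------------------
# single cell


@dataclass
class ScSimConfig:
    """Configuration of the single-cell generator.

    Defaults are the desk-scale study conditions: 5,000 cells x 2,000
    genes in 12 clusters, Treg clusters at 4.1% and 3.0% of cells.
    ``marker_panel`` is a list of ``(gene, target_cluster, fold)``
    triples; ``None`` selects the default Treg panels.  Baseline counts
    average ``baseline_mean`` per gene per cell (linear scale) before
    per-gene log-normal variation, per-cell log-normal size factors
    (``size_factor_sigma``) and per-gene-per-batch log-scale offsets
    (``batch_shift``).
    """

    n_cells: int = 5000
    n_genes: int = 2000
    n_clusters: int = 12
    treg_cluster_fracs: tuple = (0.041, 0.030)
    marker_panel: list | None = None
    baseline_mean: float = 0.5
    dispersion: float = 0.8
    n_batches: int = 2
    batch_shift: float = 0.2
    frac_mito_ribo_genes: float = 0.05
    size_factor_sigma: float = 0.3
    foxp3_gene: str = "FOXP3"
    foxp3_base_mean: float = 0.02
    foxp3_fold: float = 75.0
    signature_genes_per_cluster: int = 40
    signature_fold: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 3:
            raise ValueError("n_clusters must be >= 3")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        n_treg = len(self.treg_cluster_fracs)
        if n_treg >= self.n_clusters:
            raise ValueError("need at least one non-Treg cluster")
        for f in self.treg_cluster_fracs:
            if f * self.n_cells < 20:
                raise ValueError(
                    f"Treg cluster fraction {f} x {self.n_cells} cells gives "
                    "fewer than 20 expected cells; too small to test"
                )
        if self.marker_panel is None:
            self.marker_panel = [
                (g, c, DEFAULT_MARKER_FOLD)
                for c, panel in DEFAULT_TREG_PANELS.items()
                if c < n_treg
                for g in panel
            ]
        for gene, cluster, fold in self.marker_panel:
            if fold < 1:
                raise ValueError(f"marker {gene}: fold elevation must be >= 1")
            if not 0 <= cluster < self.n_clusters:
                raise ValueError(f"marker {gene}: no such cluster {cluster}")

    @property
    def cluster_fracs(self) -> np.ndarray:
        """Full per-cluster fraction vector (Treg clusters first)."""
        n_treg = len(self.treg_cluster_fracs)
        rest = 1.0 - sum(self.treg_cluster_fracs)
        fracs = np.concatenate(
            [
                np.asarray(self.treg_cluster_fracs, dtype=float),
                np.full(self.n_clusters - n_treg, rest / (self.n_clusters - n_treg)),
            ]
        )
        if abs(fracs.sum() - 1.0) > 1e-9:
            raise ValueError("cluster fractions must sum to 1")
        return fracs


def _gene_names(cfg: ScSimConfig, rng: np.random.Generator):
    """Assemble the gene universe: special, flagged and filler genes."""
    panel_genes = [g for g, _, _ in cfg.marker_panel]
    special = [cfg.foxp3_gene] + panel_genes
    if len(set(special)) != len(special):
        raise ValueError("marker panel gene names must be unique and not FOXP3")
    n_flag = int(round(cfg.frac_mito_ribo_genes * cfg.n_genes))
    if len(special) + n_flag > cfg.n_genes:
        raise ValueError("gene universe too small for panel plus flagged genes")
    names = np.array([f"GENE{i:05d}" for i in range(cfg.n_genes)], dtype=object)
    # place special and flagged genes at reproducible random positions
    pos = rng.choice(cfg.n_genes, size=len(special) + n_flag, replace=False)
    for i, g in enumerate(special):
        names[pos[i]] = g
    flag_pos = pos[len(special):]
    prefixes = ["MT-", "RPL", "RPS"]
    for i, p in enumerate(flag_pos):
        names[p] = f"{prefixes[i % 3]}{i:03d}"
    return names, pos[: len(special)], flag_pos


def simulate_sc_dataset(cfg: ScSimConfig):
    """Generate a single-cell count matrix plus ground truth.

    Cells are assigned to clusters multinomially by ``cluster_fracs``.
    Each non-Treg cluster carries an exclusive set of elevated
    signature genes so clusters are separable; Treg clusters are
    defined by their marker panel plus FOXP3, which is elevated
    ``foxp3_fold``-fold there and rare (< 10% of cells expressing)
    everywhere else by construction.

    Returns ``(CountMatrix, SimTruth)``.
    """
    rng = np.random.default_rng(cfg.seed)
    names, special_pos, flag_pos = _gene_names(cfg, rng)
    name_to_idx = {g: i for i, g in enumerate(names)}
    foxp3_idx = name_to_idx[cfg.foxp3_gene]

    # per-gene baselines: log-normal variation around baseline_mean
    base = cfg.baseline_mean * rng.lognormal(mean=0.0, sigma=0.5, size=cfg.n_genes)
    base[flag_pos] *= 3.0  # flagged housekeeping genes run hotter
    base[foxp3_idx] = cfg.foxp3_base_mean

    n_treg = len(cfg.treg_cluster_fracs)
    fold = np.ones((cfg.n_clusters, cfg.n_genes))
    # exclusive signature genes make non-Treg clusters separable
    reserved = set(special_pos) | set(flag_pos)
    free = np.array([i for i in range(cfg.n_genes) if i not in reserved])
    need = (cfg.n_clusters - n_treg) * cfg.signature_genes_per_cluster
    if need > len(free):
        raise ValueError("not enough genes for the per-cluster signatures")
    sig_pos = rng.choice(free, size=need, replace=False)
    planted_markers = {}
    for j, c in enumerate(range(n_treg, cfg.n_clusters)):
        block = sig_pos[
            j * cfg.signature_genes_per_cluster : (j + 1) * cfg.signature_genes_per_cluster
        ]
        fold[c, block] = cfg.signature_fold
    for gene, cluster, f in cfg.marker_panel:
        fold[cluster, name_to_idx[gene]] = f
        planted_markers.setdefault(cluster, set()).add(gene)
    for c in range(n_treg):
        fold[c, foxp3_idx] = cfg.foxp3_fold

    clusters = rng.choice(cfg.n_clusters, size=cfg.n_cells, p=cfg.cluster_fracs)
    batches = rng.integers(0, cfg.n_batches, size=cfg.n_cells)
    size = rng.lognormal(mean=0.0, sigma=cfg.size_factor_sigma, size=cfg.n_cells)
    batch_offset = np.ones((cfg.n_batches, cfg.n_genes))
    if cfg.n_batches > 1 and cfg.batch_shift > 0:
        for b in range(1, cfg.n_batches):
            batch_offset[b] = np.exp(
                rng.normal(0.0, cfg.batch_shift, size=cfg.n_genes)
            )

    mean = size[:, None] * base[None, :] * fold[clusters] * batch_offset[batches]
    counts = nb_counts(rng, mean, cfg.dispersion).astype(np.int32)
    barcodes = np.array(
        [f"CELL{i:06d}" for i in range(cfg.n_cells)], dtype=object
    )
    cm = CountMatrix(
        sp.csr_matrix(counts),
        barcodes,
        names,
        np.array([f"batch{b}" for b in batches], dtype=object),
    )
    truth = SimTruth(
        true_cluster_of_cell=clusters,
        planted_markers=planted_markers,
        true_null_genes=set(names) - {g for s in planted_markers.values() for g in s},
    )
    return cm, truth


# ---------------------------------------------------------------------------
# bulk


@dataclass
class BulkSimConfig:
    """Configuration of the bulk RNA-seq generator.

    The design is 3 CD25 groups (negative/low/high) x ``n_per_group``
    birds, sexes balanced within group.  ``lfc_low``/``lfc_high`` are
    per-gene planted log2 effects of the low/high groups relative to
    negative; ``sex_lfc`` the per-gene log2 effect of the second sex
    level.  Baseline means are log-uniform over ``mean_range``.
    """

    n_genes: int = 2000
    n_per_group: int = 4
    lfc_low: np.ndarray | None = None
    lfc_high: np.ndarray | None = None
    sex_lfc: np.ndarray | None = None
    mean_range: tuple = (20.0, 2000.0)
    dispersion: float = 0.1
    size_factor_sigma: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.mean_range[0] <= 0:
            raise ValueError("baseline means must be positive")
        for name in ("lfc_low", "lfc_high", "sex_lfc"):
            v = getattr(self, name)
            if v is None:
                v = np.zeros(self.n_genes)
            v = np.asarray(v, dtype=float)
            if v.shape != (self.n_genes,):
                raise ValueError(f"{name} must have one entry per gene")
            setattr(self, name, v)


def simulate_bulk_dataset(cfg: BulkSimConfig):
    """Generate bulk counts (genes x samples) plus metadata and truth.

    Returns ``(counts_df, meta_df, SimTruth)``; the log-mean of gene g
    in sample j is baseline + group effect + sex effect (log2 scale)
    plus the sample's log size factor.
    """
    rng = np.random.default_rng(cfg.seed)
    groups = ["negative", "low", "high"]
    samples, sex, group = [], [], []
    for gname in groups:
        for r in range(cfg.n_per_group):
            samples.append(f"{gname}_{r + 1}")
            sex.append("F" if r % 2 == 0 else "M")
            group.append(gname)
    meta = pd.DataFrame(
        {"sex": sex, "cd25_group": group},
        index=pd.Index(samples, name="sample"),
    )
    lo, hi = cfg.mean_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=cfg.n_genes))
    sf = rng.lognormal(mean=0.0, sigma=cfg.size_factor_sigma, size=len(samples))
    group_lfc = {
        "negative": np.zeros(cfg.n_genes),
        "low": cfg.lfc_low,
        "high": cfg.lfc_high,
    }
    mean = np.empty((cfg.n_genes, len(samples)))
    for j, s in enumerate(samples):
        log2_shift = group_lfc[group[j]] + (cfg.sex_lfc if sex[j] == "M" else 0.0)
        mean[:, j] = sf[j] * base * np.exp2(log2_shift)
    if (mean <= 0).any():
        raise ValueError("planted means must be positive")
    counts = nb_counts(rng, mean, cfg.dispersion)
    genes = pd.Index([f"GENE{i:05d}" for i in range(cfg.n_genes)], name="gene")
    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    null_mask = (cfg.lfc_low == 0) & (cfg.lfc_high == 0)
    truth = SimTruth(
        true_lfc={
            "low_vs_negative": dict(zip(genes, cfg.lfc_low)),
            "high_vs_negative": dict(zip(genes, cfg.lfc_high)),
        },
        true_null_genes=set(genes[null_mask]),
    )
    return counts_df, meta, truth


# ---------------------------------------------------------------------------
# qPCR


def simulate_qpcr_dataset(
    group_dcts: dict,
    noise_sd: float = 0.25,
    n_replicates: int = 4,
    seed: int = 0,
    reference_ct: float = 20.0,
) -> pd.DataFrame:
    """Generate a qPCR CT table with group-level dCT shifts.

    Per replicate the reference-gene CT is drawn around
    ``reference_ct`` and the target CT is reference + the group's true
    dCT + Gaussian noise, both with standard deviation ``noise_sd``.
    Columns: sample, group, ct_target, ct_reference.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for gname, dct in group_dcts.items():
        for r in range(n_replicates):
            ct_ref = reference_ct + rng.normal(0.0, noise_sd)
            ct_tgt = ct_ref + dct + rng.normal(0.0, noise_sd)
            rows.append(
                {
                    "sample": f"{gname}_{r + 1}",
                    "group": gname,
                    "ct_target": ct_tgt,
                    "ct_reference": ct_ref,
                }
            )
    return pd.DataFrame(rows)
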