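"""FOXP3-cluster identification and cluster marker statistics.

Two statistics drive marker calling for a candidate regulatory T cell
(Treg) cluster:

* a two-sided one-vs-rest Wilcoxon rank-sum test per gene (exact
  permutation enumeration for tiny groups, tie-corrected normal
  approximation otherwise), and
* a mean-expression-ratio score: for each gene, clusters are ordered by
  mean expression; the score is 0 unless the Treg cluster is the strict
  top cluster, otherwise it is the ratio of the Treg cluster's mean to
  the second-highest cluster's mean.

Percent-expressing is computed on the raw count layer (count > 0);
means are computed on the normalized log layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats as sps

from .bulkde import bh_adjust
from .cluster import ClusterAssignment, NormalizedMatrix
from .qc import CountMatrix

__all__ = [
    "ClusterGeneStats",
    "FoxP3CallConfig",
    "cluster_gene_stats",
    "wilcoxon_one_vs_rest",
    "wilcoxon_all_genes",
    "marker_ratio_score",
    "ratio_scores",
    "rank_markers",
    "identify_foxp3_clusters",
]

#: LFC pseudocount, matching the rank-genes convention of the single-cell
#: ecosystem: log2((expm1(mean_in) + eps) / (expm1(mean_rest) + eps))
LFC_EPS = 1e-9

#: both groups at or below this size use exact permutation enumeration
EXACT_MAX_N = 8


@dataclass
class ClusterGeneStats:
    """Per (cluster, gene) summary tables.

    ``mean_expr``: clusters x genes mean of normalized log expression.
    ``pct_expressing``: clusters x genes fraction of cells with raw
    count > 0.
    """

    mean_expr: pd.DataFrame
    pct_expressing: pd.DataFrame


@dataclass(frozen=True)
class FoxP3CallConfig:
    """Rule for calling FOXP3+ clusters.

    A cluster is called when FOXP3 is significantly elevated one-vs-rest
    (p <= ``p_threshold``, positive direction) and expressed in at least
    ``pct_threshold`` of its cells.
    """

    foxp3_gene: str = "FOXP3"
    pct_threshold: float = 0.10
    p_threshold: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.pct_threshold < 1:
            raise ValueError("pct_threshold must be in (0, 1)")


def _group_indicator(labels: np.ndarray, n_clusters: int) -> sp.csr_matrix:
    n = len(labels)
    return sp.csr_matrix(
        (np.ones(n), (labels, np.arange(n))), shape=(n_clusters, n)
    )


def cluster_gene_stats(
    nm: NormalizedMatrix, raw: CountMatrix, ca: ClusterAssignment
) -> ClusterGeneStats:
    """Mean log expression and percent-expressing per cluster and gene."""
    if nm.n_cells != len(ca.labels) or raw.n_cells != len(ca.labels):
        raise ValueError("matrices and cluster labels are not aligned")
    if nm.n_genes != raw.n_genes:
        raise ValueError("normalized and raw matrices disagree on genes")
    ind = _group_indicator(ca.labels, ca.n_clusters)
    sizes = ca.sizes().astype(float)[:, None]
    mean = np.asarray((ind @ nm.values).todense()) / sizes
    pct = np.asarray((ind @ (raw.counts > 0)).todense()) / sizes
    clusters = pd.RangeIndex(ca.n_clusters, name="cluster")
    genes = pd.Index(nm.gene_ids, name="gene")
    return ClusterGeneStats(
        pd.DataFrame(mean, index=clusters, columns=genes),
        pd.DataFrame(pct, index=clusters, columns=genes),
    )


def _exact_rank_sum_p(x_in: np.ndarray, x_rest: np.ndarray) -> float:
    """Two-sided exact permutation p for the rank-sum of ``x_in``.

    Enumerates all C(n1+n2, n1) assignments of the pooled mid-ranks, so
    ties are handled exactly.
    """
    pooled = np.concatenate([x_in, x_rest])
    ranks = sps.rankdata(pooled)
    n1 = len(x_in)
    w_obs = ranks[:n1].sum()
    mu = n1 * (ranks.sum() / len(ranks))
    dev = abs(w_obs - mu)
    hits = 0
    for idx in combinations(range(len(ranks)), n1):
        if abs(ranks[list(idx)].sum() - mu) >= dev - 1e-12:
            hits += 1
    return hits / comb(len(ranks), n1)


def _asymptotic_rank_sum(
    rank_sum_in, n1: float, n2: float, tie_term: float
):
    """Tie-corrected normal z and two-sided p from in-group rank sums.

    ``tie_term`` is sum(t^3 - t) over tie groups of the pooled sample.
    Vectorized over genes.  A zero variance (all values tied) gives p=1.
    No continuity correction: with midranks the rank-sum lattice is not
    unit-spaced, so the 0.5 correction overcorrects on tied data (checked
    against permutation oracles).
    """
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sd = np.sqrt(np.maximum(var, 0.0))
    diff = rank_sum_in - mu
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, diff / np.where(sd > 0, sd, 1), 0.0)
    p = np.minimum(2 * sps.norm.sf(np.abs(z)), 1.0)
    p = np.where(sd > 0, p, 1.0)
    return z, p


def wilcoxon_one_vs_rest(x_in, x_rest):
    """Two-sided rank-sum test of one cluster against the rest, one gene.

    Returns ``(p, direction)`` where direction is +1 when the in-cluster
    values rank higher, -1 when lower, 0 under exact balance.  Group
    sizes up to 8 on both sides are tested by exact enumeration of the
    permutation distribution; larger samples use the tie-corrected
    normal approximation.
    """
    x_in = np.asarray(x_in, dtype=float)
    x_rest = np.asarray(x_rest, dtype=float)
    n1, n2 = len(x_in), len(x_rest)
    if n1 < 1 or n2 < 1:
        raise ValueError("both groups need at least one observation")
    pooled = np.concatenate([x_in, x_rest])
    ranks = sps.rankdata(pooled)
    w = ranks[:n1].sum()
    mu = n1 * (n1 + n2 + 1) / 2.0
    direction = int(np.sign(w - mu))
    if n1 <= EXACT_MAX_N and n2 <= EXACT_MAX_N:
        return _exact_rank_sum_p(x_in, x_rest), direction
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts**3 - counts).sum())
    _, p = _asymptotic_rank_sum(np.array([w]), n1, n2, np.array([tie_term]))
    return float(p[0]), direction


def wilcoxon_all_genes(
    nm: NormalizedMatrix, ca: ClusterAssignment, cluster: int
) -> pd.DataFrame:
    """Vectorized one-vs-rest rank-sum test for every gene at once.

    Uses the tie-corrected normal approximation (the per-gene scalar
    routine is the reference for small groups).  Returns a frame indexed
    by gene with columns ``z``, ``p``, ``direction``.
    """
    in_mask = ca.labels == cluster
    n1 = int(in_mask.sum())
    n2 = nm.n_cells - n1
    if n1 < 1 or n2 < 1:
        raise ValueError("cluster and complement must both be non-empty")
    x = np.asarray(nm.values.todense())
    ranks = sps.rankdata(x, axis=0)
    rank_sum_in = ranks[in_mask].sum(axis=0)
    # tie correction per gene: count ties via sorted columns
    xs = np.sort(x, axis=0)
    n = nm.n_cells
    tie_term = np.zeros(nm.n_genes)
    for g in range(nm.n_genes):
        _, counts = np.unique(xs[:, g], return_counts=True)
        tie_term[g] = float((counts**3 - counts).sum())
    z, p = _asymptotic_rank_sum(rank_sum_in, n1, n2, tie_term)
    mu = n1 * (n + 1) / 2.0
    direction = np.sign(rank_sum_in - mu).astype(int)
    return pd.DataFrame(
        {"z": z, "p": p, "direction": direction},
        index=pd.Index(nm.gene_ids, name="gene"),
    )


def marker_ratio_score(
    stats: ClusterGeneStats, treg_cluster: int, gene
) -> float:
    """Mean-expression-ratio score of one gene for a designated cluster.

    Clusters are ordered by mean expression of the gene.  If the
    designated cluster is not the strict unique maximum the score is 0;
    otherwise it is the ratio of its mean to the second-highest
    cluster's mean.  A zero second-highest mean falls back to the
    smallest positive mean in the table as denominator (an
    "infinite-like" score that preserves ranking).
    """
    return float(ratio_scores(stats, treg_cluster, [gene])["ratio_score"].iloc[0])


def ratio_scores(
    stats: ClusterGeneStats, treg_cluster: int, genes=None
) -> pd.DataFrame:
    """Vectorized ratio score for many genes; see :func:`marker_ratio_score`."""
    means = stats.mean_expr if genes is None else stats.mean_expr[list(genes)]
    if means.shape[0] < 2:
        raise ValueError("ratio score needs at least 2 clusters")
    m = means.to_numpy()
    c = m[treg_cluster]
    others = np.delete(m, treg_cluster, axis=0)
    top_other = others.max(axis=0)
    is_strict_top = c > top_other
    positive = stats.mean_expr.to_numpy()
    positive = positive[positive > 0]
    eps = positive.min() if positive.size else np.finfo(float).tiny
    denom = np.where(top_other > 0, np.where(top_other > 0, top_other, 1.0), eps)
    score = np.where(is_strict_top, c / denom, 0.0)
    return pd.DataFrame(
        {
            "ratio_score": score,
            "infinite_like": is_strict_top & (top_other == 0),
        },
        index=means.columns,
    )


def _lfc_log_layer(mean_in: np.ndarray, mean_rest: np.ndarray) -> np.ndarray:
    return np.log2((np.expm1(mean_in) + LFC_EPS) / (np.expm1(mean_rest) + LFC_EPS))


def rank_markers(
    nm: NormalizedMatrix,
    raw: CountMatrix,
    ca: ClusterAssignment,
    treg_cluster: int,
    top_n: int | None = None,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Ranked marker table for a cluster.

    Candidate markers are genes whose BH-adjusted one-vs-rest Wilcoxon p
    is at most ``p_threshold`` and whose ratio score is positive; they
    are ordered by decreasing ratio score, ties broken by gene id.
    Columns: p_wilcoxon, padj, ratio_score, lfc, pct_in, pct_rest.
    """
    if not 0 <= treg_cluster < ca.n_clusters:
        raise ValueError(f"cluster {treg_cluster} out of range")
    stats = cluster_gene_stats(nm, raw, ca)
    wtab = wilcoxon_all_genes(nm, ca, treg_cluster)
    scores = ratio_scores(stats, treg_cluster)
    in_mask = ca.labels == treg_cluster
    n_in = in_mask.sum()
    n_rest = len(ca.labels) - n_in
    mean_in = stats.mean_expr.loc[treg_cluster].to_numpy()
    # rest-mean from cluster means weighted by size, excluding the cluster
    sizes = ca.sizes().astype(float)
    all_mean = (stats.mean_expr.to_numpy() * sizes[:, None]).sum(axis=0)
    mean_rest = (all_mean - mean_in * n_in) / n_rest
    pct_in = stats.pct_expressing.loc[treg_cluster].to_numpy()
    all_pct = (stats.pct_expressing.to_numpy() * sizes[:, None]).sum(axis=0)
    pct_rest = (all_pct - pct_in * n_in) / n_rest
    tab = pd.DataFrame(
        {
            "p_wilcoxon": wtab["p"],
            "padj": bh_adjust(wtab["p"].to_numpy()),
            "ratio_score": scores["ratio_score"],
            "infinite_like": scores["infinite_like"],
            "lfc": _lfc_log_layer(mean_in, mean_rest),
            "pct_in": pct_in,
            "pct_rest": pct_rest,
        },
        index=wtab.index,
    )
    keep = (tab["padj"] <= p_threshold) & (tab["ratio_score"] > 0)
    tab = tab[keep]
    tab = tab.sort_values(
        ["ratio_score", "gene"], ascending=[False, True], kind="stable"
    )
    return tab.head(top_n) if top_n is not None else tab


def identify_foxp3_clusters(
    nm: NormalizedMatrix,
    raw: CountMatrix,
    ca: ClusterAssignment,
    cfg: FoxP3CallConfig = FoxP3CallConfig(),
):
    """Clusters with significantly elevated, broadly expressed FOXP3.

    Returns ``(called_clusters, evidence)`` where evidence is a frame
    with one row per cluster (mean log expression, percent expressing,
    one-vs-rest p, direction, called flag).
    """
    gene_idx = np.flatnonzero(nm.gene_ids == cfg.foxp3_gene)
    if gene_idx.size == 0:
        raise ValueError(
            f"{cfg.foxp3_gene!r} is not in the filtered matrix; whitelist it "
            "during gene filtering (it is rare by nature and can fall below "
            "min_cells)"
        )
    g = int(gene_idx[0])
    values = np.asarray(nm.values[:, g].todense()).ravel()
    raw_col = np.asarray(raw.counts[:, g].todense()).ravel()
    rows = []
    for c in range(ca.n_clusters):
        in_mask = ca.labels == c
        p, direction = wilcoxon_one_vs_rest(values[in_mask], values[~in_mask])
        mean = values[in_mask].mean()
        pct = float((raw_col[in_mask] > 0).mean())
        called = (
            p <= cfg.p_threshold and direction > 0 and pct >= cfg.pct_threshold
        )
        rows.append(
            {
                "cluster": c,
                "mean_expr": mean,
                "pct_expressing": pct,
                "p_wilcoxon": p,
                "direction": direction,
                "called": called,
            }
        )
    evidence = pd.DataFrame(rows).set_index("cluster")
    called = sorted(evidence.index[evidence["called"]])
    return called, evidence
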