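"""Growth-rate-guided co-expression filtering of stage-wise expression.

Starting from gene x (stage, replicate) FPKM values and externally computed
differential-expression p-values, the pipeline applies Benjamini-Hochberg
adjustment, the expression/fold-change/FDR filter (FPKM > 1 in at least one
stage, fold change > 1.5 or < 0.67 for some stage pair, adjusted p < 0.05),
clusters standardized stage-mean trajectories by K-means, selects the
cluster whose centroid best tracks the fruit-length growth rate, and
shortlists transcription factors among its members (dropping TFs with mean
FPKM below 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

PSEUDOCOUNT = 0.1  # FPKM added before fold-change ratios


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def stage_means(expr: pd.DataFrame) -> pd.DataFrame:
    """Collapse a (stage, replicate) MultiIndex column frame to stage means."""
    if isinstance(expr.columns, pd.MultiIndex):
        return expr.T.groupby(level="stage", sort=False).mean().T
    return expr


def growth_rate_from_lengths(lengths: np.ndarray, days: np.ndarray) -> np.ndarray:
    """Growth rate as forward finite differences of fruit length.

    ``(L(t_{i+1}) - L(t_i)) / (t_{i+1} - t_i)`` assigned to stage
    ``t_{i+1}``; the returned vector has one value per stage from the second
    onward.
    """
    lengths = np.asarray(lengths, dtype=float)
    days = np.asarray(days, dtype=float)
    if len(lengths) != len(days) or len(days) < 2:
        raise ValueError("need matching length/day vectors with >= 2 stages")
    return np.diff(lengths) / np.diff(days)


@dataclass
class DEGCall:
    """Per-gene differential-expression decision."""

    table: pd.DataFrame  # gene, max_fc, min_fc, max_fpkm, padj, passed


def deg_filter(
    expr: pd.DataFrame,
    raw_p: pd.Series,
    fpkm_min: float = 1.0,
    fc_hi: float = 1.5,
    fc_lo: float = 0.67,
    alpha: float = 0.05,
) -> DEGCall:
    """Differential-expression filter on stage means.

    A gene passes iff (i) its mean FPKM exceeds ``fpkm_min`` in at least one
    stage, (ii) some stage-pair fold change (with a 0.1-FPKM pseudocount)
    exceeds ``fc_hi`` or falls below ``fc_lo``, and (iii) its BH-adjusted
    p-value is below ``alpha``.  ``raw_p`` must cover every gene in ``expr``.
    """
    means = stage_means(expr)
    missing = means.index.difference(raw_p.index)
    if len(missing) > 0:
        raise ValueError(f"missing p-values for {len(missing)} genes")
    p = raw_p.loc[means.index]
    padj = pd.Series(bh_adjust(p.to_numpy()), index=means.index)
    m = means.to_numpy() + PSEUDOCOUNT
    # extreme stage-pair ratios follow from the stage extremes
    max_fc = m.max(axis=1) / m.min(axis=1)
    min_fc = m.min(axis=1) / m.max(axis=1)
    max_fpkm = means.max(axis=1)
    passed = (
        (max_fpkm > fpkm_min)
        & ((max_fc > fc_hi) | (min_fc < fc_lo))
        & (padj < alpha)
    )
    table = pd.DataFrame(
        {
            "gene": means.index,
            "max_fc": max_fc,
            "min_fc": min_fc,
            "max_fpkm": max_fpkm.to_numpy(),
            "padj": padj.to_numpy(),
            "passed": passed.to_numpy(),
        }
    ).set_index("gene")
    return DEGCall(table)


@dataclass
class ClusterResult:
    """K-means trajectory clustering over standardized stage means."""

    assignments: pd.Series  # gene -> cluster id
    centroids: pd.DataFrame  # cluster x stage (standardized space)
    correlations: pd.Series | None = None  # cluster -> r(centroid, growth)
    selected: int | None = None


def cluster_trajectories(
    expr: pd.DataFrame,
    k: int = 6,
    seed: int = 0,
    n_init: int = 10,
) -> ClusterResult:
    """K-means on per-gene z-scored stage-mean trajectories.

    Genes with zero variance across stages are standardized to the zero
    vector.  Multiple restarts keep the best inertia; results are
    deterministic given ``seed``.
    """
    means = stage_means(expr)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(means):
        raise ValueError("k exceeds the number of genes")
    M = means.to_numpy(dtype=float)
    mu = M.mean(axis=1, keepdims=True)
    sd = M.std(axis=1, keepdims=True)
    Z = np.where(sd > 0, (M - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(Z)
    centroids = pd.DataFrame(km.cluster_centers_, columns=means.columns)
    return ClusterResult(
        assignments=pd.Series(labels, index=means.index, name="cluster"),
        centroids=centroids,
    )


def select_growth_cluster(
    result: ClusterResult,
    growth_rate: np.ndarray,
    flag_threshold: float = 0.5,
) -> ClusterResult:
    """Pick the cluster whose centroid best correlates with the growth rate.

    ``growth_rate`` may have one value per stage, or one fewer (finite
    differences aligned to stages 2..S, in which case centroids are
    correlated over those stages).  The selected cluster is the argmax of
    the Pearson correlation; all correlations are reported, and a selection
    whose best correlation falls below ``flag_threshold`` is still returned
    (callers should inspect ``correlations``).
    """
    g = np.asarray(growth_rate, dtype=float)
    C = result.centroids.to_numpy()
    n_stages = C.shape[1]
    if len(g) == n_stages:
        sub = C
    elif len(g) == n_stages - 1:
        sub = C[:, 1:]
    else:
        raise ValueError("growth_rate length must be n_stages or n_stages - 1")
    rs = np.empty(C.shape[0])
    for i in range(C.shape[0]):
        c = sub[i]
        if np.std(c) == 0 or np.std(g) == 0:
            raise ValueError("zero-variance centroid or growth vector")
        rs[i] = np.corrcoef(c, g)[0, 1]
    sel = int(np.argmax(rs))
    return ClusterResult(
        assignments=result.assignments,
        centroids=result.centroids,
        correlations=pd.Series(rs, name="r_growth"),
        selected=sel,
    )


def cluster_members(result: ClusterResult, cluster: int | None = None) -> pd.Index:
    """Genes belonging to a cluster (default: the selected one)."""
    cid = result.selected if cluster is None else cluster
    if cid is None:
        raise ValueError("no cluster selected")
    return result.assignments.index[result.assignments == cid]


def tf_shortlist(
    members: pd.Index,
    tf_annotation: pd.DataFrame,
    expr: pd.DataFrame,
    min_mean_fpkm: float = 2.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Transcription factors among the member genes, by family.

    ``tf_annotation`` maps gene -> family (columns ``gene``, ``family``).
    TFs whose overall mean FPKM is below ``min_mean_fpkm`` are dropped as
    minimally expressed.  Returns (per-TF table, family counts).
    """
    ann = tf_annotation.set_index("gene")["family"]
    tf_genes = members.intersection(ann.index)
    mean_fpkm = expr.loc[tf_genes].mean(axis=1) if len(tf_genes) else pd.Series(dtype=float)
    kept = mean_fpkm[mean_fpkm >= min_mean_fpkm].index
    table = pd.DataFrame(
        {
            "gene": kept,
            "family": ann.loc[kept].to_numpy() if len(kept) else [],
            "mean_fpkm": mean_fpkm.loc[kept].to_numpy() if len(kept) else [],
        }
    )
    counts = (
        table.groupby("family")["gene"].count().sort_values(ascending=False)
        if len(table)
        else pd.Series(dtype=int, name="gene")
    )
    return table, counts
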