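"""Coupling promoter DMR methylation to expression across stages.

For every DMR gene the three stage values of log2 expression and of DMR
methylation are Z-scored and correlated (Pearson).  Genes that are (a) DMR
genes in the context, (b) differentially expressed with a more-than-two-fold
change, and (c) strongly anticorrelated (PCC < -0.85) form the screened set,
which is then clustered on mean-centred log2 expression: a diagonal-
covariance Gaussian mixture scored by BIC chooses k, and seeded k-means with
Euclidean distance assigns clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

__all__ = [
    "zscore3",
    "gene_methylation_signal",
    "coupling_pcc",
    "coupling_table",
    "screen_candidates",
    "optimal_k",
    "cluster_genes",
    "cluster_mean_pcc",
    "seed_specific_screen",
    "ClusterResult",
]


def zscore3(values) -> np.ndarray | None:
    """Z-score a stage vector with the sample (n-1) standard deviation.

    Returns None (undefined) when the standard deviation is zero; such genes
    are excluded from the screen rather than given a fake flat profile.
    """
    x = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("stage values must be finite")
    sd = x.std(ddof=1)
    # treat numerically-constant vectors (sd at rounding-noise scale) as flat
    if sd <= 1e-12 * max(1.0, float(np.abs(x).max())):
        return None
    return (x - x.mean()) / sd


def gene_methylation_signal(
    gene_dmrs: pd.DataFrame,
    stage_level_columns: list[str],
    how: str = "mean",
) -> np.ndarray:
    """Per-stage methylation signal of one gene from its DMR windows.

    ``gene_dmrs`` holds one row per DMR window of the gene with one level
    column per stage; the signal is the mean over windows (default) or the
    single window with the largest level range (``how='max_delta'``).
    Undefined (NaN) window levels are ignored stage-wise.
    """
    if len(gene_dmrs) == 0:
        raise ValueError("gene has no DMR window in this context")
    levels = gene_dmrs[stage_level_columns].to_numpy(float)
    if how == "max_delta":
        span = np.nanmax(levels, axis=1) - np.nanmin(levels, axis=1)
        return levels[int(np.nanargmax(span))]
    if how != "mean":
        raise ValueError(f"unknown aggregation {how!r}")
    with np.errstate(invalid="ignore"):
        return np.nanmean(levels, axis=0)


def coupling_pcc(expr, meth) -> float:
    """Pearson correlation between stage expression and methylation vectors.

    Identical on raw and Z-scored inputs; callers exclude genes whose
    vectors are degenerate (zero variance).
    """
    x = np.asarray(expr, dtype=float)
    y = np.asarray(meth, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("degenerate (constant) vector: PCC undefined")
    return float(np.corrcoef(x, y)[0, 1])


def coupling_table(
    dmrs: pd.DataFrame,
    stage_level_columns: dict[str, str],
    expr_means: pd.DataFrame,
    context: str,
    pseudocount: float = 1.0,
    signal: str = "mean",
) -> pd.DataFrame:
    """Per-gene expression/methylation coupling for one context.

    ``dmrs`` is a DMR table carrying one level column per stage (named via
    ``stage_level_columns``: stage -> column); ``expr_means`` holds stage
    mean FPKM (genes x stages, same stage order).  Expression is
    log2(FPKM + pseudocount).  Genes with a degenerate expression or
    methylation trajectory are dropped.

    Returns gene_id-indexed columns: pcc, expr_z_<stage>, meth_z_<stage>,
    meth_<stage>.
    """
    stages = list(stage_level_columns)
    ctx_dmrs = dmrs[dmrs["context"] == context]
    rows = []
    for gene_id, grp in ctx_dmrs.groupby("gene_id", sort=False):
        if gene_id not in expr_means.index:
            continue
        meth = gene_methylation_signal(
            grp, [stage_level_columns[s] for s in stages], how=signal
        )
        if np.any(np.isnan(meth)):
            continue
        expr = np.log2(expr_means.loc[gene_id, stages].to_numpy(float) + pseudocount)
        ez, mz = zscore3(expr), zscore3(meth)
        if ez is None or mz is None:
            continue
        row = {"gene_id": gene_id, "context": context, "pcc": coupling_pcc(expr, meth)}
        for i, s in enumerate(stages):
            row[f"expr_z_{s}"] = ez[i]
            row[f"meth_z_{s}"] = mz[i]
            row[f"meth_{s}"] = meth[i]
        rows.append(row)
    if not rows:
        return pd.DataFrame(
            columns=["gene_id", "context", "pcc"]
        ).set_index("gene_id")
    return pd.DataFrame(rows).set_index("gene_id")


def screen_candidates(
    de_results: pd.DataFrame,
    dmr_genes: set[str],
    couplings: pd.DataFrame,
    pcc_cut: float = -0.85,
) -> set[str]:
    """Genes passing the negative-correlation screen.

    Conjunction of: DMR gene in the context; differentially expressed
    (ANOVA p below its cut) with a strictly more-than-two-fold change for at
    least one stage pair; PCC strictly below ``pcc_cut``.
    """
    dir_cols = [c for c in de_results.columns if c.startswith("direction_")]
    changed = de_results["de"] & (de_results[dir_cols] != "unchanged").any(axis=1)
    de_genes = set(de_results.index[changed])
    hit = couplings["pcc"] < pcc_cut
    return set(couplings.index[hit]) & dmr_genes & de_genes


def optimal_k(
    patterns: np.ndarray,
    k_max: int = 15,
    seed: int = 0,
) -> int:
    """Model-based optimal cluster count for expression patterns.

    Fits diagonal-covariance Gaussian mixtures for k = 1..min(k_max, n-1)
    on mean-centred patterns and returns the k with the lowest BIC.
    """
    x = np.asarray(patterns, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least two patterns")
    x = x - x.mean(axis=1, keepdims=True)
    upper = min(k_max, n - 1)
    best_k, best_bic = 1, np.inf
    for k in range(1, upper + 1):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="diag",
            random_state=seed,
            reg_covar=1e-6,
            n_init=3,
        ).fit(x)
        bic = gm.bic(x)
        if bic < best_bic - 1e-9:
            best_k, best_bic = k, bic
    return best_k


@dataclass
class ClusterResult:
    """k-means clustering of screened genes on mean-centred log2 expression."""

    k: int
    assignments: pd.Series  # gene_id -> cluster label (0..k-1)
    cluster_means: pd.DataFrame  # cluster x stage mean centred pattern
    mean_pcc: pd.Series  # cluster -> mean member PCC
    inertia: float

    def flagged_clusters(self, cut: float = -0.9) -> list[int]:
        """Clusters whose mean member PCC is below the cut."""
        return [int(c) for c in self.mean_pcc.index[self.mean_pcc < cut]]


def cluster_genes(
    patterns: pd.DataFrame,
    k: int,
    couplings: pd.DataFrame,
    seed: int = 0,
    n_init: int = 10,
) -> ClusterResult:
    """Seeded k-means (Euclidean, ``n_init`` restarts) on centred patterns.

    ``patterns`` is gene x stage log2 expression; rows are mean-centred
    before clustering, as heatmap-style cluster analyses do.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(patterns):
        raise ValueError("k cannot exceed the number of genes")
    x = patterns.to_numpy(float)
    x = x - x.mean(axis=1, keepdims=True)
    km = KMeans(n_clusters=k, n_init=n_init, max_iter=300, random_state=seed).fit(x)
    assignments = pd.Series(km.labels_, index=patterns.index, name="cluster")
    means = pd.DataFrame(km.cluster_centers_, columns=patterns.columns)
    means.index.name = "cluster"
    mean_pcc = pd.Series(
        {
            c: float(couplings.loc[idx.intersection(couplings.index), "pcc"].mean())
            for c, idx in assignments.groupby(assignments).groups.items()
        },
        name="mean_pcc",
    )
    return ClusterResult(
        k=k,
        assignments=assignments,
        cluster_means=means,
        mean_pcc=mean_pcc,
        inertia=float(km.inertia_),
    )


def cluster_mean_pcc(member_pccs) -> tuple[float, bool]:
    """(mean PCC, flagged) of one cluster; flagged when the mean is < -0.9."""
    x = np.asarray(member_pccs, dtype=float)
    if len(x) == 0:
        raise ValueError("cluster is empty")
    m = float(x.mean())
    return m, m < -0.9


def seed_specific_screen(
    screened: set[str],
    seed_specific: set[str],
    patterns: pd.DataFrame,
    couplings: pd.DataFrame,
    seed: int = 0,
    k: int | None = None,
) -> tuple[set[str], ClusterResult | None]:
    """Restrict the screen to seed-specific genes, then recluster.

    Returns the intersection and its ClusterResult (None when the subset has
    fewer than two genes; clustering a singleton is meaningless).
    """
    subset = screened & seed_specific
    if len(subset) < 2:
        return subset, None
    sub_patterns = patterns.loc[sorted(subset)]
    if k is None:
        k = optimal_k(sub_patterns.to_numpy(float), seed=seed)
    return subset, cluster_genes(sub_patterns, k, couplings, seed=seed)
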