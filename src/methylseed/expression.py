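"""Expression classification and differential expression across stages.

A gene is *expressed* when its FPKM exceeds a threshold (default 0) in at
least one examined sample.  Differential expression across the cotyledon
stages uses a per-gene one-way fixed-effects ANOVA on replicate FPKM values
at raw P < 0.05, with per-stage-pair fold changes computed on stage mean
FPKM and a strict more-than-two-fold direction call.  No multiple-testing
correction is applied to the ANOVA p-values.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix

__all__ = [
    "classify_expressed",
    "differential_expression",
    "direction_counts",
    "seed_specific_genes",
]


def classify_expressed(
    matrix: ExpressionMatrix,
    threshold: float = 0.0,
    samples: list[str] | None = None,
) -> tuple[set[str], set[str]]:
    """Partition genes into (expressed, non_expressed) sets.

    Expressed means FPKM strictly greater than ``threshold`` in at least one
    of the examined samples (all samples by default).  The two sets are
    disjoint and exhaustive.
    """
    values = matrix.values if samples is None else matrix.values[samples]
    mask = (values > threshold).any(axis=1)
    expressed = set(matrix.gene_ids[mask])
    return expressed, set(matrix.gene_ids) - expressed


def _anova_p(x: np.ndarray) -> np.ndarray:
    """Vectorised one-way ANOVA p-values.

    ``x`` has shape (genes, stages, reps).  Degenerate genes — zero
    within-group variance — get p = 0 when group means differ and p = 1 when
    they do not (no evidence either way from constant replicates).
    """
    n_genes, k, r = x.shape
    grand = x.mean(axis=(1, 2), keepdims=True)
    group = x.mean(axis=2, keepdims=True)
    ssb = r * ((group - grand) ** 2).sum(axis=(1, 2))
    ssw = ((x - group) ** 2).sum(axis=(1, 2))
    dfb, dfw = k - 1, k * (r - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (ssb / dfb) / (ssw / dfw)
    p = np.empty(n_genes)
    ok = ssw > 0
    p[ok] = stats.f.sf(f[ok], dfb, dfw)
    # with zero within-group variance, a between-group SS at rounding-noise
    # scale is no evidence of a difference
    tss = (x**2).sum(axis=(1, 2))
    real_shift = ssb > 1e-20 * np.maximum(tss, 1.0)
    p[~ok] = np.where(real_shift[~ok], 0.0, 1.0)
    return p


def differential_expression(
    matrix: ExpressionMatrix,
    p_cut: float = 0.05,
    log2_anova: bool = False,
) -> pd.DataFrame:
    """Per-gene ANOVA across cotyledon stages plus pairwise fold changes.

    Returns one row per gene: ``anova_p``, ``de`` (p < ``p_cut``), a
    ``mean_<stage>`` column per stage, and per ordered stage pair
    ``log2fc_<A>_<B>`` (log2 of mean_B/mean_A; +/-inf when one mean is zero,
    NaN when both are) and ``direction_<A>_<B>`` in
    {increased, decreased, unchanged} using a strict more-than-two-fold rule.

    ``log2_anova`` switches the ANOVA to log2(FPKM+1) replicate values.
    """
    stages = matrix.stages
    if len(stages) < 2:
        raise ValueError("need at least two stages")
    cols = [matrix.stage_columns(s) for s in stages]
    reps = {len(c) for c in cols}
    if len(reps) != 1:
        raise ValueError("unequal replicate counts across stages")
    r = reps.pop()
    if r < 2:
        raise ValueError("ANOVA needs at least two replicates per stage")
    x = np.stack([matrix.values[c].to_numpy(float) for c in cols], axis=1)
    p = _anova_p(np.log2(x + 1.0) if log2_anova else x)

    out = pd.DataFrame(index=matrix.gene_ids)
    out["anova_p"] = p
    out["de"] = p < p_cut
    means = {s: x[:, i, :].mean(axis=1) for i, s in enumerate(stages)}
    for s in stages:
        out[f"mean_{s}"] = means[s]
    for a, b in itertools.combinations(stages, 2):
        ma, mb = means[a], means[b]
        with np.errstate(divide="ignore", invalid="ignore"):
            out[f"log2fc_{a}_{b}"] = np.log2(mb) - np.log2(ma)
        inc = mb > 2.0 * ma  # strict > 2-fold; covers ma == 0, mb > 0
        dec = ma > 2.0 * mb
        direction = np.where(inc, "increased", np.where(dec, "decreased", "unchanged"))
        out[f"direction_{a}_{b}"] = direction
    return out


def direction_counts(
    de_results: pd.DataFrame, pair: tuple[str, str]
) -> tuple[int, int]:
    """(n_increased, n_decreased) among DE genes for one stage pair.

    Counts genes passing the ANOVA cut whose stage-mean fold change exceeds
    two-fold in the given direction; ``pair`` order defines increase as
    higher in the second stage.  Reversing the pair swaps the counts.
    """
    a, b = pair
    col = f"direction_{a}_{b}"
    if col in de_results.columns:
        d = de_results.loc[de_results["de"], col]
        return int((d == "increased").sum()), int((d == "decreased").sum())
    col = f"direction_{b}_{a}"
    if col not in de_results.columns:
        raise KeyError(f"no direction column for pair {pair}")
    d = de_results.loc[de_results["de"], col]
    return int((d == "decreased").sum()), int((d == "increased").sum())


def seed_specific_genes(
    matrix: ExpressionMatrix, threshold: float = 0.0
) -> set[str]:
    """Genes expressed in at least one cotyledon sample but in no leaf sample."""
    leaf_cols = matrix.leaf_columns
    if not leaf_cols:
        raise ValueError("expression matrix has no leaf sample")
    cot_cols = [c for c in matrix.values.columns if c not in leaf_cols]
    in_seed = (matrix.values[cot_cols] > threshold).any(axis=1)
    in_leaf = (matrix.values[leaf_cols] > threshold).any(axis=1)
    return set(matrix.gene_ids[in_seed & ~in_leaf])
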