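"""Promoter-window DMR calling.

Promoters are the strand-aware 4-kb regions upstream of the TSS (excluding
the TSS base), tiled with adjacent 100-bp windows anchored at the TSS;
window 0 is TSS-proximal.  Window methylation is the call-weighted level per
replicate, then the arithmetic mean over defined replicates.  A window is a
DMR between two samples when both levels are defined and differ by strictly
more than the threshold (default 30 percentage points).  Windows whose
methylation never differs between cotyledon stages are additionally
compared against leaf (the leaf-fallback rule).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import _as_index
from .models import GeneModel

__all__ = [
    "promoter_windows",
    "promoter_window_table",
    "window_levels",
    "call_dmrs",
    "leaf_fallback_dmrs",
    "map_dmr_genes",
    "dmr_gene_counts",
    "dmr_expression_enrichment",
]

DMR_COLUMNS = [
    "gene_id",
    "chrom",
    "start",
    "end",
    "window_index",
    "context",
    "stage_a",
    "stage_b",
    "level_a",
    "level_b",
    "delta",
]


def promoter_windows(
    gene: GeneModel,
    chrom_length: int,
    window: int = 100,
    promoter_length: int = 4000,
) -> list[tuple[int, int, int]]:
    """(window_index, start, end) tiles of the promoter of one gene.

    Index 0 is TSS-proximal; windows run outward.  Windows are truncated at
    the chromosome boundary and dropped when fully outside, so a TSS at the
    chromosome start can yield zero windows.
    """
    n = promoter_length // window
    out = []
    if gene.strand == "+":
        tss = gene.start
        for i in range(n):
            start = max(tss - (i + 1) * window, 0)
            end = tss - i * window
            if end > start:
                out.append((i, start, end))
    else:
        tss = gene.end
        for i in range(n):
            start = tss + i * window
            end = min(tss + (i + 1) * window, chrom_length)
            if end > start:
                out.append((i, start, end))
    return out


def promoter_window_table(
    genes: list[GeneModel],
    chrom_lengths: dict[str, int],
    window: int = 100,
    promoter_length: int = 4000,
) -> pd.DataFrame:
    """All promoter windows of all genes as one table.

    Columns: gene_id, chrom, start, end, window_index.
    """
    rows = []
    for g in genes:
        for idx, start, end in promoter_windows(
            g, chrom_lengths[g.chrom], window, promoter_length
        ):
            rows.append((g.gene_id, g.chrom, start, end, idx))
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "window_index"]
    )


def _single_sample_levels(index, windows: pd.DataFrame, context: str) -> np.ndarray:
    """Call-weighted percent per window for one library; NaN when undefined."""
    pct = np.full(len(windows), np.nan)
    for chrom, grp in windows.groupby("chrom", sort=False):
        cidx = index._by_key.get((chrom, context))
        if cidx is None:
            continue
        lo = np.searchsorted(cidx.pos, grp["start"].to_numpy(), "left")
        hi = np.searchsorted(cidx.pos, grp["end"].to_numpy(), "left")
        meth = cidx.cum_meth[hi] - cidx.cum_meth[lo]
        tot = cidx.cum_total[hi] - cidx.cum_total[lo]
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(tot > 0, 100.0 * meth / tot, np.nan)
        pct[grp.index.to_numpy()] = vals
    return pct


def window_levels(replicates, windows: pd.DataFrame, context: str) -> np.ndarray:
    """Replicate-averaged window methylation for one sample (stage or leaf).

    ``replicates`` is a sequence of cytosine tables (or indexes), one per
    library.  Each replicate's window level is computed independently and the
    defined replicate percents are averaged; a window is undefined (NaN) only
    when every replicate is undefined there.
    """
    if not replicates:
        raise ValueError("need at least one replicate library")
    per_rep = np.vstack(
        [_single_sample_levels(_as_index(r), windows, context) for r in replicates]
    )
    defined = ~np.isnan(per_rep)
    n = defined.sum(axis=0)
    sums = np.where(defined, per_rep, 0.0).sum(axis=0)
    return np.where(n > 0, sums / np.maximum(n, 1), np.nan)


def call_dmrs(
    windows: pd.DataFrame,
    levels_a,
    levels_b,
    context: str,
    stage_a: str,
    stage_b: str,
    threshold: float = 30.0,
) -> pd.DataFrame:
    """DMRs between two samples over a shared window table.

    A window qualifies when both levels are defined and
    ``abs(level_b - level_a) > threshold`` (strict).  Windows undefined in
    either sample are uncallable and silently excluded (they are neither DMR
    nor not-DMR).  Returns a table with :data:`DMR_COLUMNS`.
    """
    a = np.asarray(levels_a, dtype=float)
    b = np.asarray(levels_b, dtype=float)
    if len(a) != len(windows) or len(b) != len(windows):
        raise ValueError("level vectors must match the window table")
    callable_ = ~(np.isnan(a) | np.isnan(b))
    hit = callable_ & (np.abs(b - a) > threshold)
    out = windows.loc[hit, ["gene_id", "chrom", "start", "end", "window_index"]].copy()
    out["context"] = context
    out["stage_a"] = stage_a
    out["stage_b"] = stage_b
    out["level_a"] = a[hit]
    out["level_b"] = b[hit]
    out["delta"] = b[hit] - a[hit]
    return out.reset_index(drop=True)[DMR_COLUMNS]


def leaf_fallback_dmrs(
    windows: pd.DataFrame,
    stage_levels: dict[str, np.ndarray],
    leaf_levels,
    context: str,
    threshold: float = 30.0,
    stage_pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Leaf comparison for windows with no cotyledon stage-pair DMR.

    Windows that are a DMR in any cotyledon stage pair are excluded (the
    stage comparison takes precedence); the remainder are flagged as leaf
    DMRs when any cotyledon stage differs from leaf by more than the
    threshold.  One row is emitted per qualifying (window, stage) with
    ``stage_b='leaf'``.
    """
    stages = list(stage_levels)
    if stage_pairs is None:
        stage_pairs = [(a, b) for i, a in enumerate(stages) for b in stages[i + 1 :]]
    leaf = np.asarray(leaf_levels, dtype=float)
    already = np.zeros(len(windows), dtype=bool)
    for sa, sb in stage_pairs:
        a = np.asarray(stage_levels[sa], dtype=float)
        b = np.asarray(stage_levels[sb], dtype=float)
        already |= ~(np.isnan(a) | np.isnan(b)) & (np.abs(b - a) > threshold)
    frames = []
    for stage in stages:
        s = np.asarray(stage_levels[stage], dtype=float)
        hit = ~already & ~(np.isnan(s) | np.isnan(leaf)) & (np.abs(leaf - s) > threshold)
        sub = windows.loc[hit, ["gene_id", "chrom", "start", "end", "window_index"]].copy()
        sub["context"] = context
        sub["stage_a"] = stage
        sub["stage_b"] = "leaf"
        sub["level_a"] = s[hit]
        sub["level_b"] = leaf[hit]
        sub["delta"] = leaf[hit] - s[hit]
        frames.append(sub)
    if not frames:
        return pd.DataFrame(columns=DMR_COLUMNS)
    return pd.concat(frames, ignore_index=True)[DMR_COLUMNS]


def map_dmr_genes(dmrs: pd.DataFrame) -> set[str]:
    """Distinct genes owning at least one DMR (many windows collapse to one
    gene)."""
    if len(dmrs) == 0:
        return set()
    return set(dmrs["gene_id"].unique())


def dmr_gene_counts(dmrs: pd.DataFrame) -> pd.DataFrame:
    """DMR and DMR-gene counts per (context, stage pair)."""
    if len(dmrs) == 0:
        return pd.DataFrame(columns=["context", "stage_a", "stage_b", "n_dmrs", "n_genes"])
    grouped = dmrs.groupby(["context", "stage_a", "stage_b"], sort=False)
    out = grouped.agg(n_dmrs=("gene_id", "size"), n_genes=("gene_id", "nunique"))
    return out.reset_index()


def dmr_expression_enrichment(
    dmr_genes: set[str],
    expressed_genes: set[str],
    all_genes: set[str],
) -> dict[str, float]:
    """Preferential presence of DMRs in expressed vs non-expressed genes.

    Returns the two fractions (as percents rounded to 2 decimals) —
    DMR genes among expressed genes and among non-expressed genes — and
    their ratio, plus the underlying counts.
    """
    if not expressed_genes <= all_genes:
        raise ValueError("expressed genes must be a subset of all genes")
    non_expressed = all_genes - expressed_genes
    if not expressed_genes or not non_expressed:
        raise ValueError("both expressed and non-expressed sets must be non-empty")
    n_expr_dmr = len(dmr_genes & expressed_genes)
    n_nonexpr_dmr = len(dmr_genes & non_expressed)
    pct_expr = round(100.0 * n_expr_dmr / len(expressed_genes), 2)
    pct_nonexpr = round(100.0 * n_nonexpr_dmr / len(non_expressed), 2)
    return {
        "n_expressed_dmr_genes": n_expr_dmr,
        "n_non_expressed_dmr_genes": n_nonexpr_dmr,
        "n_expressed": len(expressed_genes),
        "n_non_expressed": len(non_expressed),
        "pct_expressed_with_dmr": pct_expr,
        "pct_non_expressed_with_dmr": pct_nonexpr,
        "ratio": pct_expr / pct_nonexpr if pct_nonexpr else float("inf"),
    }
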