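"""Genome-wide methylation quantification.

The central statistic is the call-weighted methylation level of a region:
total methylated calls divided by total evaluated calls over all
strand-specific cytosines of one context, expressed as a percent.  Regions
with zero evaluated calls are *undefined*, never 0%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix
from .models import CONTEXTS, Compartment, GeneModel, MethylationLevel

__all__ = [
    "CytosineIndex",
    "weighted_level",
    "composition_of_methylcytosines",
    "genome_window_scan",
    "window_starts",
    "conversion_rate",
    "stage_cv",
    "replicate_concordance",
    "compartment_summary",
    "stage_difference_test",
]


@dataclass
class _ContextIndex:
    pos: np.ndarray  # sorted 0-based positions
    cum_meth: np.ndarray  # prefix sums, length len(pos)+1
    cum_total: np.ndarray

    def counts(self, start: int | None = None, end: int | None = None) -> tuple[int, int]:
        lo = 0 if start is None else int(np.searchsorted(self.pos, start, "left"))
        hi = len(self.pos) if end is None else int(np.searchsorted(self.pos, end, "left"))
        return (
            int(self.cum_meth[hi] - self.cum_meth[lo]),
            int(self.cum_total[hi] - self.cum_total[lo]),
        )


class CytosineIndex:
    """Position-sorted prefix-sum index of a cytosine table.

    Supports O(log n) pooled call counts for any (chrom, context, interval)
    query; strand is pooled (strand-specific records are summed as-is).
    """

    def __init__(self, records: pd.DataFrame):
        self._by_key: dict[tuple[str, str], _ContextIndex] = {}
        if len(records) == 0:
            return
        total = records["meth"].to_numpy() + records["unmeth"].to_numpy()
        work = pd.DataFrame(
            {
                "chrom": records["chrom"].to_numpy(),
                "context": records["context"].to_numpy(),
                "pos": records["pos"].to_numpy(),
                "meth": records["meth"].to_numpy(),
                "total": total,
            }
        )
        for (chrom, context), grp in work.groupby(["chrom", "context"], sort=False):
            order = np.argsort(grp["pos"].to_numpy(), kind="stable")
            pos = grp["pos"].to_numpy()[order]
            meth = grp["meth"].to_numpy()[order]
            tot = grp["total"].to_numpy()[order]
            # duplicate positions (opposite strands) are fine: prefix sums pool them
            self._by_key[(chrom, context)] = _ContextIndex(
                pos=pos,
                cum_meth=np.concatenate([[0], np.cumsum(meth)]),
                cum_total=np.concatenate([[0], np.cumsum(tot)]),
            )

    @property
    def chroms(self) -> list[str]:
        return sorted({chrom for chrom, _ in self._by_key})

    def counts(
        self,
        context: str,
        chrom: str | None = None,
        start: int | None = None,
        end: int | None = None,
    ) -> tuple[int, int]:
        if chrom is None:
            if start is not None or end is not None:
                raise ValueError("interval query requires a chromosome")
            meth = tot = 0
            for (c, ctx), idx in self._by_key.items():
                if ctx == context:
                    m, t = idx.counts()
                    meth += m
                    tot += t
            return meth, tot
        idx = self._by_key.get((chrom, context))
        if idx is None:
            return 0, 0
        return idx.counts(start, end)

    def binned_counts(
        self, context: str, chrom: str, edges: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Pooled (meth, total) call counts in the half-open bins given by
        consecutive ``edges`` (length nbins+1, non-decreasing)."""
        idx = self._by_key.get((chrom, context))
        if idx is None:
            n = len(edges) - 1
            return np.zeros(n, dtype=np.int64), np.zeros(n, dtype=np.int64)
        cut = np.searchsorted(idx.pos, edges, "left")
        return np.diff(idx.cum_meth[cut]), np.diff(idx.cum_total[cut])


def _as_index(records) -> CytosineIndex:
    return records if isinstance(records, CytosineIndex) else CytosineIndex(records)


def weighted_level(
    records,
    context: str,
    region: tuple[str, int, int] | None = None,
) -> MethylationLevel:
    """Call-weighted percent methylation of one context, optionally within a
    half-open region ``(chrom, start, end)``.

    Pools methylated and total call counts over every strand-specific
    cytosine of the context; the level is undefined (``percent is None``)
    when no call was evaluated.
    """
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    idx = _as_index(records)
    if region is None:
        meth, total = idx.counts(context)
    else:
        chrom, start, end = region
        meth, total = idx.counts(context, chrom, start, end)
    return MethylationLevel(context=context, meth_calls=meth, total_calls=total)


def composition_of_methylcytosines(records) -> dict[str, float]:
    """Fractions of all methylated calls falling in CG / CHG / CHH.

    The three fractions sum to 1; raises when no methylated call exists.
    """
    idx = _as_index(records)
    meth = {ctx: idx.counts(ctx)[0] for ctx in CONTEXTS}
    total = sum(meth.values())
    if total == 0:
        raise ValueError("no methylated calls: composition undefined")
    return {ctx: meth[ctx] / total for ctx in CONTEXTS}


def window_starts(chrom_length: int, window_len: int, step: int) -> list[int]:
    """Start offsets of a stepped window scan over one chromosome.

    Full windows start at every multiple of ``step`` with
    ``start + window_len <= length``; a single truncated terminal window is
    appended when needed so the scan reaches the chromosome end (and is the
    only window when the chromosome is shorter than ``window_len``).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if window_len < step:
        raise ValueError("window length must be >= step")
    if chrom_length <= 0:
        raise ValueError("chromosome length must be positive")
    starts = list(range(0, max(chrom_length - window_len, 0) + 1, step))
    if not starts:
        return [0]
    if starts[-1] + window_len < chrom_length:
        starts.append(starts[-1] + step)
    return starts


def genome_window_scan(
    records,
    chrom_lengths: dict[str, int],
    window_len: int = 1_000_000,
    step: int = 100_000,
    min_calls_per_window: int = 1,
) -> pd.DataFrame:
    """Per-context methylation in stepped windows across every chromosome.

    Returns a tidy table with one row per (chrom, window, context):
    columns ``chrom, start, end, context, meth, total, percent``; ``percent``
    is NaN for windows with fewer than ``min_calls_per_window`` evaluated
    calls (undefined, not 0%).
    """
    idx = _as_index(records)
    out = []
    for chrom, length in chrom_lengths.items():
        starts = np.asarray(window_starts(length, window_len, step))
        ends = np.minimum(starts + window_len, length)
        for context in CONTEXTS:
            cidx = idx._by_key.get((chrom, context))
            if cidx is None:
                meth = tot = np.zeros(len(starts), dtype=np.int64)
            else:
                lo = np.searchsorted(cidx.pos, starts, "left")
                hi = np.searchsorted(cidx.pos, ends, "left")
                meth = cidx.cum_meth[hi] - cidx.cum_meth[lo]
                tot = cidx.cum_total[hi] - cidx.cum_total[lo]
            with np.errstate(invalid="ignore", divide="ignore"):
                pct = np.where(
                    tot >= max(min_calls_per_window, 1), 100.0 * meth / tot, np.nan
                )
            out.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": starts,
                        "end": ends,
                        "context": context,
                        "meth": meth,
                        "total": tot,
                        "percent": pct,
                    }
                )
            )
    return pd.concat(out, ignore_index=True)


def conversion_rate(spike_records) -> float:
    """Bisulfite conversion rate, in percent, from an unmethylated spike-in.

    Every methylated call on the spike-in genome is a conversion failure, so
    the rate is ``100 * unmeth / (meth + unmeth)`` pooled over all contexts.
    """
    idx = _as_index(spike_records)
    meth = tot = 0
    for ctx in CONTEXTS:
        m, t = idx.counts(ctx)
        meth += m
        tot += t
    if tot == 0:
        raise ValueError("no calls on spike-in: conversion rate undefined")
    return 100.0 * (tot - meth) / tot


def stage_cv(stage_levels) -> float:
    """Coefficient of variation (percent) across stage-level values.

    Sample (n-1) standard deviation over the mean, times 100.
    """
    x = np.asarray(stage_levels, dtype=float)
    if len(x) < 2:
        raise ValueError("CV needs at least two values")
    if np.any(x < 0):
        raise ValueError("levels must be non-negative")
    mean = x.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return 100.0 * x.std(ddof=1) / mean


def replicate_concordance(levels_rep1, levels_rep2) -> float:
    """R-squared (squared Pearson correlation) between paired region levels.

    Pairs where either replicate is undefined (NaN) are dropped; at least
    three defined pairs are required.  Returns NaN when either vector has
    zero variance (undefined, flagged rather than raised).
    """
    a = np.asarray(levels_rep1, dtype=float)
    b = np.asarray(levels_rep2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("replicate vectors must be paired")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if len(a) < 3:
        raise ValueError("need at least 3 defined paired levels")
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def compartment_summary(
    records,
    compartments: list[Compartment],
    genes: list[GeneModel],
    expression: ExpressionMatrix | None = None,
    expressed_threshold: float = 0.0,
) -> pd.DataFrame:
    """Per-compartment methylation, gene density and expression summary.

    One row per compartment label with the call-weighted level per context,
    genes per Mb, expressed genes per Mb and mean FPKM of contained genes
    (genes are assigned to the compartment containing their TSS).  Mirrors
    the pericentromere-versus-arm contrast tables of plant methylomes.
    """
    idx = _as_index(records)
    by_label: dict[str, list[Compartment]] = {}
    for comp in compartments:
        by_label.setdefault(comp.label, []).append(comp)
    # overlap check within chromosomes
    by_chrom: dict[str, list[Compartment]] = {}
    for comp in compartments:
        by_chrom.setdefault(comp.chrom, []).append(comp)
    for chrom, items in by_chrom.items():
        items = sorted(items, key=lambda c: c.start)
        for x, y in zip(items, items[1:]):
            if y.start < x.end:
                raise ValueError(f"overlapping compartments on {chrom}")

    expressed: set[str] = set()
    mean_fpkm: pd.Series | None = None
    if expression is not None:
        mean_fpkm = expression.values.mean(axis=1)
        expressed = set(
            expression.gene_ids[(expression.values > expressed_threshold).any(axis=1)]
        )

    def _gene_compartment(gene: GeneModel) -> str | None:
        # assignment by TSS; for a - strand gene the TSS boundary may equal
        # the compartment end, so fall back to the last body base
        probe = gene.tss if gene.strand == "+" else gene.end - 1
        for comp in by_chrom.get(gene.chrom, []):
            if comp.start <= probe < comp.end:
                return comp.label
        return None

    rows = []
    for label, comps in by_label.items():
        mb = sum(c.length for c in comps) / 1e6
        row: dict = {"label": label, "megabases": mb}
        for context in CONTEXTS:
            meth = tot = 0
            for c in comps:
                m, t = idx.counts(context, c.chrom, c.start, c.end)
                meth += m
                tot += t
            row[f"{context}_percent"] = 100.0 * meth / tot if tot else np.nan
        members = [g for g in genes if _gene_compartment(g) == label]
        row["genes_per_mb"] = len(members) / mb if mb else np.nan
        if expression is not None:
            n_expr = sum(1 for g in members if g.gene_id in expressed)
            row["expressed_genes_per_mb"] = n_expr / mb if mb else np.nan
            fpkms = [
                mean_fpkm.loc[g.gene_id]
                for g in members
                if g.gene_id in mean_fpkm.index
            ]
            row["mean_fpkm"] = float(np.mean(fpkms)) if fpkms else 0.0
        rows.append(row)
    return pd.DataFrame(rows).set_index("label")


def stage_difference_test(window_levels_a, window_levels_b) -> float:
    """Two-sided Wilcoxon rank-sum p-value comparing per-window levels.

    NaN (undefined-window) entries are dropped; each sample needs >= 3
    defined values.  Fully tied data yields p = 1.
    """
    a = np.asarray(window_levels_a, dtype=float)
    b = np.asarray(window_levels_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each sample needs at least 3 defined window levels")
    stat, p = stats.ranksums(a, b)
    return float(p)
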