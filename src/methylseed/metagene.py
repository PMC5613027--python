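"""Metagene end analysis: averaged methylation across feature bodies and
4-kb flanks.

Each feature body is rescaled to 100 equal bins (5' to 3' in transcription
orientation); each flank is tiled with 100 fixed 40-bp bins anchored at the
TSS/TTS.  Per-bin levels pool methylated/total calls across all features
(call-weighted), which keeps low-coverage features from dominating.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import CytosineIndex, stage_cv, _as_index
from .models import TE_CLASSES, GeneModel, MetageneProfile, TEModel

__all__ = [
    "gene_end_profile",
    "te_end_profile",
    "profile_cv_across_stages",
    "profile_table",
]

_N_BINS = 100
_FLANK = 4000


def _body_edges(start: int, end: int, n_bins: int) -> np.ndarray:
    """Exact equal-partition bin edges of [start, end) floored to integers.

    Edge i is start + floor(i * L / n_bins); consecutive edges tile the body
    with no gaps or overlap.
    """
    length = end - start
    i = np.arange(n_bins + 1, dtype=np.int64)
    return start + (i * length) // n_bins


def _feature_bin_counts(
    index: CytosineIndex,
    context: str,
    chrom: str,
    chrom_length: int,
    start: int,
    end: int,
    strand: str,
    n_bins: int,
    flank: int,
) -> tuple[np.ndarray, np.ndarray]:
    """(meth, total) call counts in the 3*n_bins oriented bins of one feature."""
    bin_bp = flank // n_bins
    # genomic (unoriented) edges; clip to the chromosome so edge bins that
    # fall off the end contribute zero calls
    left = np.arange(start - flank, start + 1, bin_bp)
    body = _body_edges(start, end, n_bins)
    right = np.arange(end, end + flank + 1, bin_bp)
    meths, tots = [], []
    for edges in (left, body, right):
        e = np.clip(edges, 0, chrom_length)
        m, t = index.binned_counts(context, chrom, e)
        meths.append(m)
        tots.append(t)
    meth = np.concatenate(meths)
    tot = np.concatenate(tots)
    if strand == "-":
        # transcription orientation runs right-to-left: reverse bin order so
        # bin 0 is 4 kb upstream of the TSS
        meth = meth[::-1]
        tot = tot[::-1]
    return meth, tot


def _pooled_profile(
    records,
    features,
    context: str,
    chrom_lengths: dict[str, int],
    feature_class: str,
    n_bins: int,
    flank: int,
) -> MetageneProfile:
    index = _as_index(records)
    meth = np.zeros(3 * n_bins, dtype=np.int64)
    tot = np.zeros(3 * n_bins, dtype=np.int64)
    n_used = n_skipped = 0
    for feat in features:
        if feat.length < n_bins:
            n_skipped += 1
            continue
        if feat.chrom not in chrom_lengths:
            raise ValueError(f"unknown chromosome {feat.chrom!r}")
        m, t = _feature_bin_counts(
            index,
            context,
            feat.chrom,
            chrom_lengths[feat.chrom],
            feat.start,
            feat.end,
            feat.strand,
            n_bins,
            flank,
        )
        meth += m
        tot += t
        n_used += 1
    return MetageneProfile(
        context=context,
        feature_class=feature_class,
        meth=meth,
        total=tot,
        n_features=n_used,
        n_skipped=n_skipped,
        n_bins=n_bins,
    )


def gene_end_profile(
    records,
    genes: list[GeneModel],
    context: str,
    chrom_lengths: dict[str, int],
    n_bins: int = _N_BINS,
    flank: int = _FLANK,
) -> MetageneProfile:
    """Pooled methylation profile over gene bodies and 4-kb TSS/TTS flanks.

    Bodies shorter than ``n_bins`` bp are skipped (they cannot host 100
    non-empty equal bins); the skip count is recorded on the profile.
    """
    return _pooled_profile(
        records, genes, context, chrom_lengths, "gene", n_bins, flank
    )


def te_end_profile(
    records,
    tes: list[TEModel],
    context: str,
    chrom_lengths: dict[str, int],
    te_class: str,
    n_bins: int = _N_BINS,
    flank: int = _FLANK,
) -> MetageneProfile:
    """Pooled profile over transposons of one class plus 4-kb flanks."""
    if te_class not in TE_CLASSES:
        raise ValueError(f"unknown TE class {te_class!r}")
    members = [t for t in tes if t.te_class == te_class]
    if not members:
        raise ValueError(f"no transposons of class {te_class!r}")
    return _pooled_profile(
        records, members, context, chrom_lengths, te_class, n_bins, flank
    )


def profile_cv_across_stages(profiles: dict[str, MetageneProfile]) -> dict[str, float]:
    """Coefficient of variation of stage-wise zone levels across profiles.

    ``profiles`` maps stage name to a same-shape MetageneProfile; the return
    maps zone (``up``/``body``/``down``/``flank``) to the CV (percent) of the
    stage-wise call-weighted zone level, ``flank`` pooling both flanks.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two stage profiles")
    shapes = {p.meth.shape for p in profiles.values()}
    if len(shapes) != 1:
        raise ValueError("stage profiles have mismatched shapes")
    stages = list(profiles)
    out = {}
    for zone in ("up", "body", "down"):
        out[zone] = stage_cv([profiles[s].zone_percent(zone) for s in stages])
    flank_levels = []
    for s in stages:
        p = profiles[s]
        mask = p.zones != "body"
        tot = p.total[mask].sum()
        if tot == 0:
            raise ValueError("no evaluated flank calls")
        flank_levels.append(100.0 * p.meth[mask].sum() / tot)
    out["flank"] = stage_cv(flank_levels)
    return out


def profile_table(profile: MetageneProfile) -> pd.DataFrame:
    """Tidy export: feature_class, context, bin_index, bin_zone, percent, calls."""
    return pd.DataFrame(
        {
            "feature_class": profile.feature_class,
            "context": profile.context,
            "bin_index": np.arange(3 * profile.n_bins),
            "bin_zone": profile.zones,
            "percent": profile.percent,
            "calls": profile.total,
        }
    )
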