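"""End-to-end orchestration of the analysis stages over a scenario directory.

A scenario directory (as written by :func:`methylseed.simulate.simulate_scenario`)
holds per-library cytosine reports plus annotation, expression and GO-map
files.  :func:`run_pipeline` executes genome summary -> window scan ->
metagene -> DMR calling -> differential expression -> coupling screen and
clustering -> GO enrichment, writes one TSV per stage into the run
directory, and finishes with a manifest recording the configuration hash
and row counts so runs are auditable and diffable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import core, dmr as dmr_mod, enrichment as enr_mod, expression as expr_mod
from . import integration as integ_mod, metagene as meta_mod
from .io import (
    read_compartment_bed,
    read_cx_report,
    read_expression_tsv,
    read_gff3_genes,
    read_go_map,
    read_te_bed,
)
from .models import CONTEXTS, TE_CLASSES
from .simulate import COTYLEDON_STAGES, WGBS_LIBRARIES

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

STAGE_PAIRS = [("S2", "S6"), ("S6", "S8"), ("S2", "S8")]


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; serialized to the run directory."""

    input_dir: str
    output_dir: str
    dmr_threshold: float = 30.0
    dmr_window: int = 100
    promoter_length: int = 4000
    pcc_cut: float = -0.85
    de_p: float = 0.05
    fold: float = 2.0
    expressed_fpkm: float = 0.0
    enrichment_alpha: float = 0.01
    scan_window: int = 1_000_000
    scan_step: int = 100_000
    metagene_flank: int = 4000
    min_calls_per_window: int = 1
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _load_libraries(indir: Path) -> dict[str, list]:
    """Per-tissue list of cytosine indexes (one per library)."""
    libs: dict[str, list] = {}
    for tissue, rep in WGBS_LIBRARIES:
        path = indir / f"cx_{tissue}_{rep}.txt"
        if not path.exists():
            raise FileNotFoundError(f"missing cytosine report {path}")
        libs.setdefault(tissue, []).append(core.CytosineIndex(read_cx_report(path)))
    return libs


def _pool_counts(indexes: list, context: str) -> tuple[int, int]:
    meth = tot = 0
    for idx in indexes:
        m, t = idx.counts(context)
        meth += m
        tot += t
    return meth, tot


def run_pipeline(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Execute every stage; returns the stage tables and writes them as TSV."""
    indir = Path(config.input_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "config_hash": config.config_hash()}
    outputs: dict[str, pd.DataFrame] = {}

    def _emit(name: str, table: pd.DataFrame) -> None:
        table.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
        outputs[name] = table
        manifest.setdefault("row_counts", {})[name] = int(len(table))
        logger.info("stage %s: %d rows", name, len(table))

    # ------------------------------------------------------------------ load
    libs = _load_libraries(indir)
    genes = read_gff3_genes(indir / "genes.gff3")
    tes = read_te_bed(indir / "te.bed")
    compartments = read_compartment_bed(indir / "compartments.bed")
    matrix = read_expression_tsv(indir / "expression.tsv")
    go_map = read_go_map(indir / "go_map.tsv")
    chrom_lengths: dict[str, int] = {}
    for comp in compartments:
        chrom_lengths[comp.chrom] = max(chrom_lengths.get(comp.chrom, 0), comp.end)

    # --------------------------------------------------------------- summary
    rows = []
    for tissue, indexes in libs.items():
        for context in CONTEXTS:
            per_rep = []
            for rep, idx in enumerate(indexes, start=1):
                m, t = idx.counts(context)
                pct = 100.0 * m / t if t else np.nan
                rows.append(
                    {
                        "tissue": tissue,
                        "replicate": rep,
                        "context": context,
                        "meth_calls": m,
                        "total_calls": t,
                        "percent": pct,
                    }
                )
                if t:
                    per_rep.append(pct)
            rows.append(
                {
                    "tissue": tissue,
                    "replicate": 0,  # 0 = replicate average
                    "context": context,
                    "meth_calls": np.nan,
                    "total_calls": np.nan,
                    "percent": float(np.mean(per_rep)) if per_rep else np.nan,
                }
            )
    _emit("summary", pd.DataFrame(rows))

    spike_path = indir / "spike_in.txt"
    if spike_path.exists():
        spike = read_cx_report(spike_path)
        rate = core.conversion_rate(spike)
        manifest["conversion_rate_percent"] = rate
        logger.info("spike-in conversion rate %.2f%%", rate)

    # ----------------------------------------------------------- window scan
    scan_frames = []
    for tissue, indexes in libs.items():
        pooled = pd.concat(
            [
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": ci.pos,
                        "meth": np.diff(ci.cum_meth),
                        "unmeth": np.diff(ci.cum_total) - np.diff(ci.cum_meth),
                        "context": context,
                    }
                )
                for idx in indexes
                for (chrom, context), ci in idx._by_key.items()
            ],
            ignore_index=True,
        )
        pooled["strand"] = "+"
        pooled["tricontext"] = ""
        scan = core.genome_window_scan(
            pooled,
            chrom_lengths,
            config.scan_window,
            config.scan_step,
            config.min_calls_per_window,
        )
        scan.insert(0, "tissue", tissue)
        scan_frames.append(scan)
    _emit("windows", pd.concat(scan_frames, ignore_index=True))

    # -------------------------------------------------------------- metagene
    meta_frames = []
    for tissue, indexes in libs.items():
        # pool replicate libraries for profiles (per-bin call weighting)
        merged = indexes if len(indexes) == 1 else indexes
        for context in CONTEXTS:
            profiles = []
            prof = None
            for idx in merged:
                p = meta_mod.gene_end_profile(
                    idx, genes, context, chrom_lengths, flank=config.metagene_flank
                )
                prof = p if prof is None else _merge_profiles(prof, p)
            table = meta_mod.profile_table(prof)
            table.insert(0, "tissue", tissue)
            meta_frames.append(table)
            for te_class in TE_CLASSES:
                prof = None
                for idx in merged:
                    p = meta_mod.te_end_profile(
                        idx,
                        tes,
                        context,
                        chrom_lengths,
                        te_class,
                        flank=config.metagene_flank,
                    )
                    prof = p if prof is None else _merge_profiles(prof, p)
                table = meta_mod.profile_table(prof)
                table.insert(0, "tissue", tissue)
                meta_frames.append(table)
    _emit("metagene", pd.concat(meta_frames, ignore_index=True))

    # ------------------------------------------------------------------ DMRs
    windows = dmr_mod.promoter_window_table(
        genes, chrom_lengths, config.dmr_window, config.promoter_length
    )
    level_tables: dict[str, pd.DataFrame] = {}
    all_dmrs = []
    for context in CONTEXTS:
        levels = windows.copy()
        for tissue in list(COTYLEDON_STAGES) + ["leaf"]:
            levels[f"level_{tissue}"] = dmr_mod.window_levels(
                libs[tissue], windows, context
            )
        level_tables[context] = levels
        stage_levels = {s: levels[f"level_{s}"].to_numpy() for s in COTYLEDON_STAGES}
        for sa, sb in STAGE_PAIRS:
            all_dmrs.append(
                dmr_mod.call_dmrs(
                    windows,
                    stage_levels[sa],
                    stage_levels[sb],
                    context,
                    sa,
                    sb,
                    config.dmr_threshold,
                )
            )
        all_dmrs.append(
            dmr_mod.leaf_fallback_dmrs(
                windows,
                stage_levels,
                levels["level_leaf"].to_numpy(),
                context,
                config.dmr_threshold,
                STAGE_PAIRS,
            )
        )
    dmrs = pd.concat(all_dmrs, ignore_index=True)
    _emit("dmrs", dmrs)
    _emit("dmr_gene_counts", dmr_mod.dmr_gene_counts(dmrs))

    expressed, _non = expr_mod.classify_expressed(matrix, config.expressed_fpkm)
    all_gene_ids = {g.gene_id for g in genes}
    enrich_rows = []
    stage_dmrs = dmrs[dmrs["stage_b"] != "leaf"]
    for (context, sa, sb), grp in stage_dmrs.groupby(
        ["context", "stage_a", "stage_b"], sort=False
    ):
        stats = dmr_mod.dmr_expression_enrichment(
            dmr_mod.map_dmr_genes(grp), expressed & all_gene_ids, all_gene_ids
        )
        enrich_rows.append({"context": context, "stage_a": sa, "stage_b": sb, **stats})
    _emit("dmr_expression_enrichment", pd.DataFrame(enrich_rows))

    # ------------------------------------------------- differential expression
    de = expr_mod.differential_expression(matrix, p_cut=config.de_p)
    _emit("differential_expression", de.reset_index())

    # ------------------------------------------------------------ integration
    expr_means = matrix.stage_means()
    stage_cols = {s: f"level_{s}" for s in COTYLEDON_STAGES}
    coupling_frames, cluster_rows, assign_frames = [], [], []
    for context in CONTEXTS:
        ctx_dmrs = stage_dmrs[stage_dmrs["context"] == context]
        if len(ctx_dmrs) == 0:
            continue
        keys = ctx_dmrs[["gene_id", "window_index"]].drop_duplicates()
        dmr_windows = keys.merge(
            level_tables[context], on=["gene_id", "window_index"], how="left"
        )
        dmr_windows["context"] = context
        couplings = integ_mod.coupling_table(
            dmr_windows, stage_cols, expr_means, context
        )
        if len(couplings) == 0:
            continue
        coupling_frames.append(couplings.reset_index())
        screened = integ_mod.screen_candidates(
            de, dmr_mod.map_dmr_genes(ctx_dmrs), couplings, config.pcc_cut
        )
        logger.info("%s: %d genes pass the coupling screen", context, len(screened))
        if len(screened) < 2:
            continue
        patterns = np.log2(expr_means.loc[sorted(screened)] + 1.0)
        k = integ_mod.optimal_k(patterns.to_numpy(), seed=config.seed)
        result = integ_mod.cluster_genes(patterns, k, couplings, seed=config.seed)
        assign = result.assignments.reset_index()
        assign.columns = ["gene_id", "cluster"]
        assign.insert(0, "context", context)
        assign_frames.append(assign)
        for c in range(k):
            members = result.assignments[result.assignments == c]
            cluster_rows.append(
                {
                    "context": context,
                    "cluster": c,
                    "size": len(members),
                    "mean_pcc": result.mean_pcc.get(c, np.nan),
                    "k": k,
                }
            )
    _emit(
        "couplings",
        pd.concat(coupling_frames, ignore_index=True)
        if coupling_frames
        else pd.DataFrame(columns=["gene_id", "context", "pcc"]),
    )
    _emit(
        "clusters",
        pd.DataFrame(cluster_rows, columns=["context", "cluster", "size", "mean_pcc", "k"]),
    )
    _emit(
        "cluster_assignments",
        pd.concat(assign_frames, ignore_index=True)
        if assign_frames
        else pd.DataFrame(columns=["context", "gene_id", "cluster"]),
    )

    # ------------------------------------------------------------- enrichment
    background = set(go_map["gene_id"]) & all_gene_ids
    screened_chh: set = set()
    if assign_frames:
        for frame in assign_frames:
            if (frame["context"] == "CHH").any():
                screened_chh = set(frame.loc[frame["context"] == "CHH", "gene_id"])
    selection = screened_chh & background
    if selection:
        table = enr_mod.go_enrichment(
            selection, background, go_map, alpha=config.enrichment_alpha
        )
    else:
        table = pd.DataFrame(columns=enr_mod.ENRICHMENT_COLUMNS)
    _emit("go_enrichment", table)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return outputs


def _merge_profiles(a, b):
    """Pool two same-shape metagene profiles (replicate libraries)."""
    if a.meth.shape != b.meth.shape or a.context != b.context:
        raise ValueError("profiles are not poolable")
    from .models import MetageneProfile

    return MetageneProfile(
        context=a.context,
        feature_class=a.feature_class,
        meth=a.meth + b.meth,
        total=a.total + b.total,
        n_features=a.n_features,
        n_skipped=a.n_skipped,
        n_bins=a.n_bins,
    )
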