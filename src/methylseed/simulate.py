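"""Synthetic-data generator for the seed-maturation methylome pipeline.

The generator emulates the statistical structure of a plant seed WGBS +
RNA-seq study: a small genome with pericentromeric and arm compartments,
genes placed preferentially on arms, transposons preferentially in the
pericentromere, strand-specific cytosine sites in the three contexts, and
an FPKM matrix in which a configurable fraction of genes has expression
negatively coupled to its promoter CHH methylation across the three
maturation stages.

Methylation truth is a per-site probability assembled from (tissue,
context, zone): chromosome arms, pericentromere, gene bodies, gene flanks,
TE bodies, and the promoters of planted coupled genes.  Observed calls
fold bisulfite non-conversion into apparent methylation of unmethylated
cytosines — the dominant artifact and the one the spike-in control can
see; sequencing miscalls are not modelled.  Stage presets pin the
genome-average levels to the study's headline values (66% CG / 45% CHG /
9% CHH cotyledon average; CHH 6% at S2 rising to 10%/11% at S6/S8; 4% in
leaf) and the compartment contrast to the pericentromere-vs-arm table.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    write_cx_report,
    write_expression_tsv,
    write_gff3_genes,
    write_go_map,
    write_intervals_bed,
)
from .models import CONTEXTS, TE_CLASSES, Compartment, GeneModel, TEModel

__all__ = [
    "SimulationConfig",
    "Genome",
    "stage_presets",
    "generate_genome",
    "simulate_methylome",
    "simulate_uniform_sites",
    "simulate_preset_context",
    "simulate_spike_in",
    "simulate_expression",
    "simulate_scenario",
    "WGBS_LIBRARIES",
]

# zone codes painted along each chromosome
_ARM, _PERI, _FLANK, _BODY, _TE, _COUPLED = 0, 1, 2, 3, 4, 5

#: WGBS library layout: two replicates at S2 and S6, one at S8 and leaf.
WGBS_LIBRARIES = [("S2", 1), ("S2", 2), ("S6", 1), ("S6", 2), ("S8", 1), ("leaf", 1)]

COTYLEDON_STAGES = ("S2", "S6", "S8")


@dataclass(frozen=True)
class StagePreset:
    """Per-context true methylation probabilities for one tissue.

    ``genome`` holds the flat genome-average probabilities used by the
    uniform simulation mode; ``zones`` maps zone name -> context -> p for
    the structured genome.
    """

    name: str
    genome: dict[str, float]
    zones: dict[str, dict[str, float]]


def _preset(name, genome, arm, peri, body, flank, te) -> StagePreset:
    def z(cg, chg, chh):
        return {"CG": cg, "CHG": chg, "CHH": chh}

    return StagePreset(
        name=name,
        genome=z(*genome),
        zones={
            "arm": z(*arm),
            "pericentromere": z(*peri),
            "gene_body": z(*body),
            "gene_flank": z(*flank),
            "te_body": z(*te),
        },
    )


def stage_presets() -> dict[str, StagePreset]:
    """Named tissue presets: leaf, S2, S6, S8 and the cotyledon average.

    Genome averages follow the study's headline levels: CG 66% and CHG 45%
    in cotyledons at every stage, CHH rising 6% -> 10% -> 11% from S2 to S8,
    and leaf lowest at 4% CHH.  Compartment values follow the
    pericentromere-vs-arm contrast (CG 85 vs 31, CHG 65 vs 17, CHH 13 vs 6
    at mid-maturation), with CHH scaled across stages in proportion to the
    genome-average trajectory.  Gene flanks carry the stage-responsive CHH
    signal (5% at S2 to ~10% at S8, 2.5% in leaf); bodies stay low; TE
    bodies are heavily CG/CHG methylated (>80%).
    """
    return {
        "S2": _preset(
            "S2",
            genome=(0.66, 0.45, 0.06),
            arm=(0.31, 0.17, 0.036),
            peri=(0.85, 0.65, 0.078),
            body=(0.35, 0.08, 0.02),
            flank=(0.35, 0.15, 0.05),
            te=(0.85, 0.80, 0.10),
        ),
        "S6": _preset(
            "S6",
            genome=(0.66, 0.45, 0.10),
            arm=(0.31, 0.17, 0.06),
            peri=(0.85, 0.65, 0.13),
            body=(0.35, 0.08, 0.02),
            flank=(0.35, 0.15, 0.09),
            te=(0.85, 0.80, 0.16),
        ),
        "S8": _preset(
            "S8",
            genome=(0.66, 0.45, 0.11),
            arm=(0.31, 0.17, 0.066),
            peri=(0.85, 0.65, 0.143),
            body=(0.35, 0.08, 0.02),
            flank=(0.35, 0.15, 0.10),
            te=(0.85, 0.80, 0.18),
        ),
        "leaf": _preset(
            "leaf",
            genome=(0.66, 0.40, 0.04),
            arm=(0.31, 0.15, 0.024),
            peri=(0.85, 0.58, 0.052),
            body=(0.35, 0.07, 0.01),
            flank=(0.35, 0.13, 0.025),
            te=(0.85, 0.71, 0.06),
        ),
        "cotyledon": _preset(
            "cotyledon",
            genome=(0.66, 0.45, 0.09),
            arm=(0.31, 0.17, 0.054),
            peri=(0.85, 0.65, 0.117),
            body=(0.35, 0.08, 0.02),
            flank=(0.35, 0.15, 0.08),
            te=(0.85, 0.80, 0.146),
        ),
    }


@dataclass
class SimulationConfig:
    """Desk-scale study scenario: defaults run the full pipeline in minutes.

    The defaults encode the study conditions: 10x Poisson coverage, 0.995
    bisulfite conversion, a 4:1 arm-to-pericentromere gene density ratio,
    TEs concentrated in the pericentromere, three cotyledon stages plus
    leaf, three RNA replicates per stage, and a planted fraction of genes
    whose promoter CHH methylation rises across maturation while their
    expression falls (pre-noise PCC exactly -1, eight-fold span).
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 2_000_000
    pericentromere_fraction: float = 0.4
    n_genes: int = 800
    gene_length_range: tuple[int, int] = (1000, 3000)
    arm_density_ratio: float = 4.0  # genes per Mb, arm : pericentromere
    n_tes_per_class: int = 100
    te_length_range: tuple[int, int] = (500, 2000)
    te_peri_fraction: float = 0.7
    sites_per_kb: dict[str, float] = field(
        default_factory=lambda: {"CG": 8.0, "CHG": 8.0, "CHH": 25.0}
    )
    coverage: float = 10.0
    conversion_rate: float = 0.995
    promoter_length: int = 4000
    # planted promoter-CHH trajectory of coupled genes over (S2, S6, S8)
    coupled_meth: tuple[float, float, float] = (0.05, 0.25, 0.50)
    coupled_fraction: float = 0.10
    coupled_log2_span: float = 1.5  # log2 units per methylation z-unit
    de_fraction: float = 0.15
    de_fold: float = 4.0
    silent_fraction: float = 0.25
    seed_specific_fraction: float = 0.10
    expr_log2_mean: float = 3.0
    expr_log2_sd: float = 2.0
    replicate_cv: float = 0.10
    n_expr_replicates: int = 3
    n_go_terms: int = 40
    spike_in_length: int = 48_502  # lambda phage genome

    def validate(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not 0 < self.conversion_rate <= 1:
            raise ValueError("conversion rate must be in (0, 1]")
        for p in (
            self.pericentromere_fraction,
            self.te_peri_fraction,
            self.coupled_fraction,
            self.de_fraction,
            self.silent_fraction,
            self.seed_specific_fraction,
            *self.coupled_meth,
        ):
            if not 0 <= p <= 1:
                raise ValueError(f"probability/fraction {p} outside [0, 1]")


@dataclass
class Genome:
    """A generated genome plus the ground truth needed to score recovery."""

    config: SimulationConfig
    chrom_lengths: dict[str, int]
    compartments: list[Compartment]
    genes: list[GeneModel]
    tes: list[TEModel]
    sites: pd.DataFrame  # chrom, pos, strand, context, tricontext, zone
    go_map: pd.DataFrame
    coupled_genes: list[str]
    de_genes: list[str]
    silent_genes: list[str]
    seed_specific_genes: list[str]

    def truth_dict(self) -> dict:
        return {
            "chrom_lengths": self.chrom_lengths,
            "coupled_genes": self.coupled_genes,
            "coupled_meth": list(self.config.coupled_meth),
            "de_genes": self.de_genes,
            "silent_genes": self.silent_genes,
            "seed_specific_genes": self.seed_specific_genes,
            "config": {
                k: v if not isinstance(v, tuple) else list(v)
                for k, v in asdict(self.config).items()
            },
        }


# ---------------------------------------------------------------------------
# genome construction


def _place_nonoverlapping(
    lengths: np.ndarray, start: int, end: int, rng: np.random.Generator
) -> np.ndarray:
    """Random non-overlapping placement of features in [start, end).

    Distributes the free space as multinomial integer gaps around the
    features (uniform over arrangements); raises when the features do not
    fit.
    """
    total = int(lengths.sum())
    free = (end - start) - total
    if free < 0:
        raise ValueError(
            f"cannot place features of total length {total} in "
            f"[{start}, {end}) — too many features for the region"
        )
    n = len(lengths)
    if n == 0:
        return np.array([], dtype=np.int64)
    gaps = rng.multinomial(free, np.full(n + 1, 1.0 / (n + 1)))
    starts = start + np.cumsum(gaps[:-1]) + np.concatenate([[0], np.cumsum(lengths[:-1])])
    return starts.astype(np.int64)


def _compartment_regions(config: SimulationConfig) -> list[Compartment]:
    comps = []
    half_gap = config.pericentromere_fraction / 2
    for i in range(config.n_chroms):
        chrom = f"Chr{i + 1}"
        length = config.chrom_length
        a = int(length * (0.5 - half_gap))
        b = int(length * (0.5 + half_gap))
        comps.append(Compartment(chrom, 0, a, "non_pericentromeric"))
        if b > a:
            comps.append(Compartment(chrom, a, b, "pericentromeric"))
        comps.append(Compartment(chrom, b, length, "non_pericentromeric"))
    return comps


def _allocate(counts_total: int, weights: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Integer allocation of features to regions proportional to weights."""
    w = weights / weights.sum()
    return rng.multinomial(counts_total, w)


_TRI_CHOICES = {
    "CG": ["CGA", "CGT", "CGC", "CGG"],
    "CHG": ["CAG", "CTG", "CCG"],
    "CHH": ["CAT", "CTA", "CAA", "CTT", "CAC", "CTC"],
}


def generate_genome(config: SimulationConfig) -> Genome:
    """Build chromosomes, compartments, genes, TEs, cytosine sites, GO map.

    Genes are allocated to compartment regions with an arm:pericentromere
    density ratio (default 4:1) and placed without overlap; TEs are placed
    in the space between, preferentially in the pericentromere.  Cytosine
    site positions are drawn uniformly (context labels assigned, not
    derived from sequence).  Deterministic under the config seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    comps = _compartment_regions(config)

    # --- genes and TEs share one non-overlap placement per region
    regions = [(c.chrom, c.start, c.end, c.label) for c in comps]
    gene_weights = np.array(
        [
            (r[2] - r[1])
            * (config.arm_density_ratio if r[3] == "non_pericentromeric" else 1.0)
            for r in regions
        ]
    )
    gene_alloc = _allocate(config.n_genes, gene_weights, rng)
    n_tes = config.n_tes_per_class * len(TE_CLASSES)
    te_weights = np.array(
        [
            (r[2] - r[1])
            * (
                config.te_peri_fraction
                if r[3] == "pericentromeric"
                else 1.0 - config.te_peri_fraction
            )
            for r in regions
        ]
    )
    te_alloc = _allocate(n_tes, te_weights, rng)

    genes: list[GeneModel] = []
    tes: list[TEModel] = []
    g_lo, g_hi = config.gene_length_range
    t_lo, t_hi = config.te_length_range
    te_classes = rng.permutation(np.repeat(TE_CLASSES, config.n_tes_per_class))
    te_cursor = 0
    for (chrom, start, end, _label), n_g, n_t in zip(regions, gene_alloc, te_alloc):
        gene_lens = rng.integers(g_lo, g_hi + 1, size=n_g)
        te_lens = rng.integers(t_lo, t_hi + 1, size=n_t)
        lengths = np.concatenate([gene_lens, te_lens])
        kinds = np.array(["gene"] * n_g + ["te"] * n_t)
        order = rng.permutation(len(lengths))
        starts = _place_nonoverlapping(lengths[order], start, end, rng)
        for s, ln, kind in zip(starts, lengths[order], kinds[order]):
            if kind == "gene":
                genes.append(
                    GeneModel(
                        gene_id=f"Gene{len(genes) + 1:05d}",
                        chrom=chrom,
                        strand="+" if rng.random() < 0.5 else "-",
                        start=int(s),
                        end=int(s + ln),
                    )
                )
            else:
                tes.append(
                    TEModel(
                        te_id=f"TE{len(tes) + 1:05d}",
                        chrom=chrom,
                        start=int(s),
                        end=int(s + ln),
                        te_class=str(te_classes[te_cursor]),
                        strand="+" if rng.random() < 0.5 else "-",
                    )
                )
                te_cursor += 1

    chrom_lengths = {f"Chr{i + 1}": config.chrom_length for i in range(config.n_chroms)}

    # --- planted gene roles (assigned before painting so coupled promoters
    # can be zoned)
    gene_ids = [g.gene_id for g in genes]
    n = len(gene_ids)
    perm = rng.permutation(n)
    n_silent = int(round(config.silent_fraction * n))
    silent = [gene_ids[i] for i in perm[:n_silent]]
    expressed = [gene_ids[i] for i in perm[n_silent:]]
    n_coupled = int(round(config.coupled_fraction * n))
    coupled = expressed[:n_coupled]
    rest = expressed[n_coupled:]
    n_de = int(round(config.de_fraction * n))
    de = rest[:n_de]
    n_ss = int(round(config.seed_specific_fraction * n))
    seed_specific = list(rng.choice(expressed, size=min(n_ss, len(expressed)), replace=False))

    # --- zone painting (priority: coupled promoter > TE body > gene body
    # > gene flank > compartment background)
    zones = {c: np.zeros(l, dtype=np.uint8) for c, l in chrom_lengths.items()}
    for comp in comps:
        if comp.label == "pericentromeric":
            zones[comp.chrom][comp.start : comp.end] = _PERI
    flank = config.promoter_length
    for g in genes:
        z = zones[g.chrom]
        z[max(g.start - flank, 0) : g.start] = _FLANK
        z[g.end : min(g.end + flank, len(z))] = _FLANK
    for g in genes:
        zones[g.chrom][g.start : g.end] = _BODY
    for t in tes:
        zones[t.chrom][t.start : t.end] = _TE
    coupled_set = set(coupled)
    by_id = {g.gene_id: g for g in genes}
    for gid in coupled:
        g = by_id[gid]
        z = zones[g.chrom]
        if g.strand == "+":
            z[max(g.start - flank, 0) : g.start] = _COUPLED
        else:
            z[g.end : min(g.end + flank, len(z))] = _COUPLED

    # --- cytosine sites
    frames = []
    for chrom, length in chrom_lengths.items():
        for context in CONTEXTS:
            n_sites = int(config.sites_per_kb[context] * length / 1000)
            pos = np.sort(
                rng.choice(length, size=min(n_sites, length), replace=False)
            )
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": pos,
                        "strand": np.where(rng.random(len(pos)) < 0.5, "+", "-"),
                        "context": context,
                        "tricontext": rng.choice(_TRI_CHOICES[context], size=len(pos)),
                        "zone": zones[chrom][pos],
                    }
                )
            )
    sites = (
        pd.concat(frames, ignore_index=True)
        .sort_values(["chrom", "pos"], kind="stable")
        .reset_index(drop=True)
    )

    # --- GO map: uniform background terms plus a few terms biased toward
    # coupled genes so enrichment has signal to find
    go_rows = []
    n_terms = config.n_go_terms
    term_ids = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    biased = set(term_ids[:3])
    for gid in gene_ids:
        k = rng.poisson(2.0)
        terms = set(rng.choice(term_ids, size=min(k, n_terms), replace=False))
        if gid in coupled_set:
            for t in term_ids[:3]:
                if rng.random() < 0.4:
                    terms.add(t)
        for t in sorted(terms):
            label = "coupling-biased" if t in biased else "background"
            go_rows.append((gid, t, f"synthetic {label} term {t[-4:]}"))
    go_map = pd.DataFrame(go_rows, columns=["gene_id", "go_id", "go_description"])

    return Genome(
        config=config,
        chrom_lengths=chrom_lengths,
        compartments=comps,
        genes=genes,
        tes=tes,
        sites=sites,
        go_map=go_map,
        coupled_genes=coupled,
        de_genes=de,
        silent_genes=silent,
        seed_specific_genes=seed_specific,
    )


# ---------------------------------------------------------------------------
# methylome simulation


def _apparent_p(p_true: np.ndarray, conversion_rate: float) -> np.ndarray:
    # unconverted unmethylated cytosines read as methylated
    return p_true + (1.0 - conversion_rate) * (1.0 - p_true)


def _draw_calls(
    p_true: np.ndarray,
    coverage: float,
    conversion_rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    depth = rng.poisson(coverage, size=len(p_true))
    meth = rng.binomial(depth, _apparent_p(p_true, conversion_rate))
    return meth, depth - meth


def simulate_methylome(
    genome: Genome,
    tissue: str,
    seed: int,
    coverage: float | None = None,
    conversion_rate: float | None = None,
) -> pd.DataFrame:
    """One WGBS library for a tissue over the genome's fixed site map.

    Per site, depth ~ Poisson(coverage) and methylated calls ~
    Binomial(depth, apparent p), where the apparent probability folds
    non-conversion into the true zone probability of the tissue preset.
    Zero-depth sites are kept (cytosine reports list them with 0/0 calls).
    """
    presets = stage_presets()
    if tissue not in presets:
        raise ValueError(f"unknown tissue {tissue!r}; choose from {sorted(presets)}")
    preset = presets[tissue]
    cfg = genome.config
    coverage = cfg.coverage if coverage is None else coverage
    conversion_rate = cfg.conversion_rate if conversion_rate is None else conversion_rate
    rng = np.random.default_rng(seed)

    zone_names = {
        _ARM: "arm",
        _PERI: "pericentromere",
        _FLANK: "gene_flank",
        _BODY: "gene_body",
        _TE: "te_body",
    }
    sites = genome.sites
    p_true = np.empty(len(sites))
    zone = sites["zone"].to_numpy()
    ctx = sites["context"].to_numpy()
    for code, zname in zone_names.items():
        for context in CONTEXTS:
            mask = (zone == code) & (ctx == context)
            p_true[mask] = preset.zones[zname][context]
    # coupled promoters: CHH follows the planted stage trajectory
    stage_idx = {"S2": 0, "S6": 1, "S8": 2}
    for context in CONTEXTS:
        mask = (zone == _COUPLED) & (ctx == context)
        if context == "CHH" and tissue in stage_idx:
            p_true[mask] = cfg.coupled_meth[stage_idx[tissue]]
        else:
            p_true[mask] = preset.zones["gene_flank"][context]

    meth, unmeth = _draw_calls(p_true, coverage, conversion_rate, rng)
    return pd.DataFrame(
        {
            "chrom": sites["chrom"],
            "pos": sites["pos"],
            "strand": sites["strand"],
            "meth": meth,
            "unmeth": unmeth,
            "context": sites["context"],
            "tricontext": sites["tricontext"],
        }
    )


def simulate_uniform_sites(
    p_true: float,
    n_sites: int,
    context: str,
    coverage: float,
    conversion_rate: float,
    seed: int,
    chrom: str = "ChrU",
) -> pd.DataFrame:
    """Flat-truth methylome: ``n_sites`` cytosines of one context sharing a
    single true methylation probability.  Used for genome-average recovery
    checks where spatial structure is irrelevant."""
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    rng = np.random.default_rng(seed)
    meth, unmeth = _draw_calls(
        np.full(n_sites, float(p_true)), coverage, conversion_rate, rng
    )
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(n_sites, dtype=np.int64) * 2,
            "strand": np.where(rng.random(n_sites) < 0.5, "+", "-"),
            "meth": meth,
            "unmeth": unmeth,
            "context": context,
            "tricontext": rng.choice(_TRI_CHOICES[context], size=n_sites),
        }
    )


def simulate_preset_context(
    tissue: str,
    context: str,
    n_sites: int,
    seed: int,
    coverage: float = 10.0,
    conversion_rate: float = 0.995,
) -> pd.DataFrame:
    """Uniform-mode methylome at a stage preset's genome-average probability."""
    presets = stage_presets()
    if tissue not in presets:
        raise ValueError(f"unknown tissue {tissue!r}")
    return simulate_uniform_sites(
        presets[tissue].genome[context],
        n_sites,
        context,
        coverage,
        conversion_rate,
        seed,
    )


def simulate_spike_in(
    n_sites: int = 5000,
    coverage: float = 10.0,
    conversion_rate: float = 0.995,
    seed: int = 0,
    length: int = 48_502,
) -> pd.DataFrame:
    """Unmethylated spike-in genome (lambda-like): p_true = 0 everywhere.

    Methylated calls arise only from conversion failure, so the measured
    conversion rate estimates ``conversion_rate``.  Defaults give roughly
    n_sites * coverage = 50,000 evaluated calls.
    """
    if not 0 < conversion_rate <= 1:
        raise ValueError("conversion rate must be in (0, 1]")
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(length, size=min(n_sites, length), replace=False))
    context = rng.choice(CONTEXTS, size=len(pos), p=[0.15, 0.15, 0.70])
    meth, unmeth = _draw_calls(np.zeros(len(pos)), coverage, conversion_rate, rng)
    tri = np.array([rng.choice(_TRI_CHOICES[c]) for c in context])
    return pd.DataFrame(
        {
            "chrom": "lambda",
            "pos": pos,
            "strand": np.where(rng.random(len(pos)) < 0.5, "+", "-"),
            "meth": meth,
            "unmeth": unmeth,
            "context": context,
            "tricontext": tri,
        }
    )


# ---------------------------------------------------------------------------
# expression simulation


def simulate_expression(genome: Genome, seed: int) -> ExpressionMatrix:
    """FPKM matrix: three replicates per cotyledon stage plus one leaf sample.

    Baseline FPKM is log-normal; replicate noise is multiplicative
    log-normal at the configured CV.  Planted DE genes get a fold shift in
    a random subset of stages; coupled genes get stage means whose log2
    trajectory is an exact negative linear function of their planted
    promoter-CHH trajectory (pre-noise PCC -1); silent genes are zero
    everywhere; seed-specific genes are zeroed in leaf.
    """
    cfg = genome.config
    rng = np.random.default_rng(seed)
    gene_ids = [g.gene_id for g in genome.genes]
    n = len(gene_ids)
    idx = {gid: i for i, gid in enumerate(gene_ids)}

    base_log2 = rng.normal(cfg.expr_log2_mean, cfg.expr_log2_sd, size=n)
    stage_log2 = np.tile(base_log2[:, None], (1, 3))

    meth = np.asarray(cfg.coupled_meth, dtype=float)
    mz = (meth - meth.mean()) / meth.std(ddof=1)
    for gid in genome.coupled_genes:
        stage_log2[idx[gid]] = base_log2[idx[gid]] - cfg.coupled_log2_span * mz
    log2_fold = np.log2(cfg.de_fold)
    for gid in genome.de_genes:
        which = rng.integers(0, 3)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        stage_log2[idx[gid], which] += sign * log2_fold

    silent = np.zeros(n, dtype=bool)
    for gid in genome.silent_genes:
        silent[idx[gid]] = True

    sigma = np.sqrt(np.log1p(cfg.replicate_cv**2))
    columns, data = [], []
    for s, stage in enumerate(COTYLEDON_STAGES):
        for rep in range(1, cfg.n_expr_replicates + 1):
            noise = rng.lognormal(0.0, sigma, size=n)
            vals = np.where(silent, 0.0, 2.0**stage_log2[:, s] * noise)
            columns.append(f"cotyledon_{stage}_{rep}")
            data.append(vals)
    leaf_zero = silent.copy()
    for gid in genome.seed_specific_genes:
        leaf_zero[idx[gid]] = True
    noise = rng.lognormal(0.0, sigma, size=n)
    data.append(np.where(leaf_zero, 0.0, 2.0**base_log2 * noise))
    columns.append("leaf_leaf_1")

    values = pd.DataFrame(
        np.column_stack(data), index=pd.Index(gene_ids, name="gene_id"), columns=columns
    )
    samples = {}
    for col in columns:
        tissue, stage, rep = col.split("_")
        samples[col] = (tissue, stage, int(rep))
    return ExpressionMatrix(values=values, samples=samples)


# ---------------------------------------------------------------------------
# scenario emission


def simulate_scenario(config: SimulationConfig, outdir: str | Path) -> Genome:
    """Generate a full study scenario and write every pipeline input.

    Emits per-library cytosine reports (``cx_<tissue>_<rep>.txt``),
    ``genes.gff3``, ``te.bed``, ``compartments.bed``, ``spike_in.txt``,
    ``expression.tsv``, ``go_map.tsv`` and ``truth.json``.  Identical
    config and seed reproduce identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = generate_genome(config)
    seeds = np.random.SeedSequence(config.seed).generate_state(len(WGBS_LIBRARIES) + 2)
    seeds = [int(s % (2**31)) for s in seeds]
    for (tissue, rep), s in zip(WGBS_LIBRARIES, seeds):
        records = simulate_methylome(genome, tissue, seed=s)
        write_cx_report(records, outdir / f"cx_{tissue}_{rep}.txt")
    spike = simulate_spike_in(
        coverage=config.coverage,
        conversion_rate=config.conversion_rate,
        seed=seeds[len(WGBS_LIBRARIES)],
        length=config.spike_in_length,
    )
    write_cx_report(spike, outdir / "spike_in.txt")
    matrix = simulate_expression(genome, seed=seeds[len(WGBS_LIBRARIES) + 1])
    write_expression_tsv(matrix, outdir / "expression.tsv")
    write_gff3_genes(genome.genes, outdir / "genes.gff3")
    write_intervals_bed(genome.tes, outdir / "te.bed")
    write_intervals_bed(genome.compartments, outdir / "compartments.bed")
    write_go_map(genome.go_map, outdir / "go_map.tsv")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(genome.truth_dict(), fh, indent=1)
    return genome
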