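# Methods

## Scope and data model

The package operates downstream of read alignment and methylation
extraction: its inputs are per-cytosine call tables (7-column cytosine
reports with 1-based positions), a GFF3 gene annotation, BED interval
files for transposons (with class labels Helitron/LINE/LTR/TIR) and
chromosome compartments (pericentromeric vs non-pericentromeric), a
gene × sample FPKM matrix, and a gene→GO map. Call counts are taken as
given; any read-end trimming applied by the upstream extractor is assumed
to have happened before the table was written.

Internally every coordinate is 0-based half-open; the 1-based cytosine
report and GFF3 conventions are converted at the read/write boundary only,
which removes a whole class of off-by-one bugs in window arithmetic.
Strand-specific records are kept as-is — symmetric CG sites are *not*
collapsed — and all region statistics pool calls across strands.

## Methylation quantification

The methylation level of a region is call-weighted: total methylated
calls over total evaluated calls, as a percent. This weighting follows
the definition "bases methylated over bases evaluated" rather than a mean
of per-site fractions, so deeply covered sites carry proportionally more
weight and low-coverage sites cannot dominate. A region with zero
evaluated calls is *undefined* and excluded from downstream comparisons —
reporting it as 0% would fabricate hypomethylation. No per-site binomial
methylation caller is implemented: every downstream statistic consumes
pooled counts, and the composition statistic (share of methylated calls
per context) likewise counts calls, not sites.

A `min_calls_per_window` knob (default 1, i.e. no filter) lets users
require minimum coverage in window scans.

Chromosome scans use 1-Mb windows stepped every 100 kb. Full windows
start at every step offset whose window fits on the chromosome; a single
truncated terminal window is appended only when needed to reach the
chromosome end (and is the only window on chromosomes shorter than the
window length).

Stage variability uses the coefficient of variation with the sample
(n−1) standard deviation; replicate concordance is the squared Pearson
correlation over paired region levels (undefined when either vector is
constant); stage comparisons of window-level distributions use the
two-sided Wilcoxon rank-sum test on 1-Mb window levels. The test unit
(1-Mb windows) is a package choice; any per-region level table can be
passed instead.

## Metagene end analysis

Each feature body is split into 100 equal bins with exact integer edge
arithmetic (edge i at ⌊i·L/100⌋), so bins tile the body with no gap or
overlap; bodies shorter than 100 bp are skipped and counted. Each 4-kb
flank is tiled with 100 fixed 40-bp bins anchored at the TSS/TTS and
ordered in transcription orientation, so profiles read left to right
from −4 kb through the body to +4 kb. Per-bin aggregation pools calls
across features (call-weighted) rather than averaging per-feature
percentages: with a 40-bp bin at 10× coverage a single feature
contributes only a handful of calls, and averaging per-feature
percentages would let near-empty features inject large variance.
Flank bins clipped off a chromosome end contribute zero calls.

## Promoter DMR calling

Promoters are strand-aware 4-kb regions immediately upstream of the TSS,
excluding the TSS base, tiled with forty adjacent 100-bp windows anchored
at each gene's TSS (window 0 TSS-proximal). Overlap with a neighbouring
gene's body is not masked. Edge windows truncated by the chromosome
boundary are kept if they retain any evaluable cytosine.

Window levels are computed per replicate library and the defined
replicate percents averaged (percent-averaging, not count-pooling,
mirrors how replicate values are usually combined after per-library
processing); single-library samples use the library as-is. A window is a
DMR between two samples when both levels are defined and differ by
strictly more than 30 percentage points. Windows undefined in either
sample are uncallable — excluded from both the DMR and the not-DMR sets.
Windows with no cotyledon stage-pair DMR are additionally compared
against leaf at the same threshold (leaf-fallback rule); stage DMRs take
precedence. A gene owning at least one DMR window is a DMR gene; counts
are reported per context and stage pair, and the expressed vs
non-expressed DMR-gene fractions are reported as percents with two
decimals plus their ratio.

## Expression analysis

A gene is expressed when FPKM exceeds a threshold (default 0, strict) in
at least one examined sample. Differential expression across the three
cotyledon stages uses a per-gene one-way fixed-effects ANOVA on raw FPKM
replicate values at raw P < 0.05 with no multiple-testing correction (a
`log2_anova` switch applies log₂(FPKM+1) first). When every replicate
within every stage is identical, a between-group sum of squares at
floating-point rounding scale is treated as zero (p = 1) rather than as
an infinitely significant effect. Fold changes are computed on stage-mean
FPKM with no pseudocount; direction calls are strict (> 2-fold), and a
zero mean against a positive mean counts as changed (infinite fold).
Seed-specific genes are expressed in at least one cotyledon sample and in
no leaf sample.

## Coupling screen and clustering

Expression trajectories are log₂(stage-mean FPKM + 1); the pseudocount
is forced by zero-FPKM stages. A gene's methylation trajectory is the
stage-wise mean over its DMR windows (a max-range-window alternative is
selectable). Both trajectories are Z-scored with the sample SD; genes
with a numerically constant trajectory (SD at rounding-noise scale) are
excluded rather than given fabricated flat profiles. The screen is the
strict conjunction: DMR gene, differentially expressed with > 2-fold
change, Pearson r < −0.85. With only three stage points the PCC is
granular and no p-value is attached to it.

Cluster count selection fits diagonal-covariance Gaussian mixtures for
k = 1..min(15, n−1) on mean-centred patterns and takes the BIC minimum —
a model-based criterion of the mclust family, seeded and restarted
(3 initialisations). Clustering itself is k-means with Euclidean
distance, 10 restarts, 300 iterations, fixed seed; per-cluster mean
member PCC is reported and clusters below −0.9 flagged. The
seed-specific variant intersects the screen with seed-specific genes and
reclusters the subset.

## GO enrichment

Hypergeometric tails per term: upper tail P(X ≥ k) when the observed
count exceeds its expectation K·n/N, lower tail otherwise. The
background is the set of annotated genes supplied in the map;
annotations are taken as given with no GO-graph ancestor propagation.
Correction is Benjamini–Hochberg by default (Bonferroni selectable — the
correction method behind published "corrected probability" columns is
rarely stated, so both are exposed); significance is corrected p < 0.01.

## Synthetic-data generator

The generator emulates the study design: two chromosomes of 2 Mb with a
central pericentromeric compartment (40% of each chromosome), ~800 genes
placed without overlap at a 4:1 arm:pericentromere density ratio, ~400
transposons (100 per class) preferentially in the pericentromere,
strand-specific cytosine sites drawn uniformly with context labels
assigned by density (CHH sites outnumber CG/CHG roughly 3:1, as in an
AT-rich genome), 10× Poisson coverage and 0.995 bisulfite conversion.
WGBS libraries follow the study layout — two replicates at S2 and S6,
single libraries at S8 and leaf; RNA-seq has three replicates per
cotyledon stage plus one leaf sample.

Methylation truth is a per-site probability looked up by (tissue,
context, zone). Genome averages are pinned to the headline stage levels
(CG 66%, CHG 45% in cotyledons; CHH 6%/10%/11% at S2/S6/S8; leaf 4% CHH)
and the compartment contrast to the pericentromere-vs-arm table (CG
85 vs 31, CHG 65 vs 17, CHH 13 vs 6 at mid-maturation), with CHH zone
values scaled across stages in proportion to the genome trajectory. Gene
flanks carry the stage-responsive CHH signal (5% → ~10%); bodies stay
low; TE bodies are ≥80% CG/CHG methylated. The error model folds
non-conversion into apparent methylation of unmethylated cytosines — the
artifact the spike-in control measures; sequencing miscalls are not
modelled. The spike-in is an unmethylated lambda-sized genome.

A configurable 10% of genes are *coupled*: their promoter CHH follows a
planted trajectory (5% → 25% → 50%) while their log₂ expression is an
exact negative linear function of it (pre-noise PCC −1, eight-fold
span). Planted DE genes shift one random stage four-fold; 25% of genes
are silent; 10% are zeroed in leaf (seed-specific pool). Replicate noise
is multiplicative log-normal at CV 0.1. Everything is deterministic
under the config seed, and `truth.json` records every planted set.

What passing recovery tests shows — and does not. The generator has no
real sequence, no mappability or coverage biases, no correlated errors
between neighbouring sites, and its coupling is planted noiselessly; so
recovery demonstrates that the estimators and the screen are correct
under the stated sampling model, not that the thresholds would achieve
the same sensitivity on real libraries.

## Problem sizes

Default scenarios are desk-scale by design: the full default scenario
(≈164k sites × 6 libraries) simulates and runs through every stage in
well under a minute, and the recovery checks use 200k sites per context
at 10× — large enough that binomial error (SE ≈ 0.03 points) is far
inside the half-point tolerances used in tests.

## Known limitations

- No FDR control on DMR calls (plain 30-point threshold) and no
  statistical test per window; the caller reproduces a thresholding
  procedure, not a calibrated detector.
- The window-level false-positive behaviour under the null follows the
  binomial sampling model; sparse windows (one or two covered cytosines)
  are the dominant source of chance DMRs. With three stage points, some
  unplanted genes clear the PCC screen by chance; on the default
  scenario this touches a small percent of non-coupled genes.
- Gaussian-mixture BIC is one member of the model-based-selection
  family; other covariance families can prefer different k on the same
  data, so published cluster counts need not be reproduced exactly.
- GO enrichment treats annotations as independent labels; no
  topology-aware (elim-style) correction.
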