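# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions.

## Coordinates and the data model

Internally every interval is 0-based half-open; BED files on disk keep
that convention and the bismark-style cytosine report is the only 1-based
boundary.  A CpG is the dyad keyed by its plus-strand C: plus- and
minus-strand calls are merged by summing counts at load time.  Merging is
idempotent and order-independent, and is justified because every
downstream statistic pools counts within a region anyway.  Zero-coverage
CpGs are retained in memory but contribute nothing to pooled levels.

## Tile statistics

Chromosomes are partitioned into consecutive 500 bp tiles; the terminal
partial tile is kept (dropping it would silently discard chromosome
ends).  A tile's methylation level in a sample is the pooled ratio
Σmeth/Σtotal over its CpGs — pooling counts, not averaging per-CpG
levels, weights each read equally and is the definition the rest of the
analysis assumes.  The genome-wide level of a sample is the unweighted
mean over its non-missing tile levels; tiles, not CpGs, are the unit of
the genome-wide summary.

Per-CpG category fractions use the boundaries high > 0.8, low in
(0, 0.2), none = 0.  The stated open intervals leave the value 0.8 itself
unclaimed; we close the intermediate bin at the top, [0.2, 0.8], and note
it here as a convention.

## DMR calling

The test unit is the per-replicate tile level (n = 3 per group),
matching the replicate design; testing individual CpGs would ignore
replicate variance.  Before testing, counts are re-pooled over the
intersection of CpG sites covered (total > 0) in **every** sample of both
groups, the strict reading of "sites recovered by both groups"; tiles
with fewer than `min_shared_cpg` (default 3, configurable — no minimum is
inherent to the definition) shared sites are reported untested.

The test is the unpaired two-tailed equal-variance Student's t
(deliberately not Welch), BH-adjusted over all tested tiles of one
comparison.  A tile is a DMR when |mean_b − mean_a| > 0.2 **and**
adjusted p < 0.05, both strict inequalities.  Degenerate zero-variance
tiles get p = 1 (equal means) or p = 0 (unequal means, logged).
Adjacent significant tiles are not merged, so DMR counts are tile counts.
Direction is hyper when group_b is higher; swapping the groups flips
every direction label.

## Six-pattern clustering

DMRs from the two adjacent-stage comparisons are pooled; each DMR's
(EC, HEC, HSPC) profile of sibling group means is min–max normalised and
assigned to the nearest of six canonical centroids (Euclidean, ties to
the lowest cluster index): C1 (0, ½, 1) gradual gain, C2 (0, 0, 1),
C3 (1, 0, 1), C4 (0, 1, 0), C5 (0, 1, 1), C6 (1, 1, 0).  The rule-based
assignment is the default because it is deterministic and auditable; a
seeded k-means backend (k = 6 on the same normalised profiles, clusters
relabelled by nearest canonical centroid) is provided for sensitivity
analysis.  Neither backend claims to reproduce any particular published
heatmap, whose clustering algorithm is not specified.  Profiles with a
missing cell-type level are reported unassigned.

## Annotation and enrichment

Gene models are gene-level: the outermost transcript span defines the
gene, exons are unioned across transcripts.  Promoters are strand-aware
TSS − 1 kb to TSS + 1 kb, clipped at chromosome bounds; gene bodies run
TSS→TES.  A DMR overlapping ≥ 1 bp of a feature is assignable to it; the
single label uses the fixed precedence promoter > exon > intron >
intergenic (a reported distribution needs one label per region; the
precedence is a documented convention).  Repeat classes and CpG islands
are supported as user-supplied BED feature sets rather than bundled.

Region-set enrichment is the one-sided Fisher exact test on the 2×2
table (query vs rest of universe) × (overlaps feature vs not), BH-corrected
across feature sets.  The universe is the set of *tested* tiles, not the
whole genome: conditioning on testability removes coverage bias.

## Expression and integration

Differential expression is deliberately a transparent engine:
median-of-ratios size factors (computed over genes expressed in every
sample), a two-sample t-test on log2(normalised + 1), BH correction, and
the selection rule adjusted p < `deg_alpha` with |log2FC| ≥ 1 from
pseudocount-1 group means.  It does not reimplement negative-binomial
shrinkage; it is a simple, auditable stand-in with the same thresholds.
`deg_alpha` defaults to 0.05.

Integration computes, per DEG and genotype, the Pearson correlation
between measured promoter methylation and log2 expression across the
genotype's nine samples (3 cell types × 3 replicates; within-cell-type
correlation at n = 3 would be meaningless).  A gene is selected when the
sibling correlation is < −0.3 and the mutant shows no such correlation
("no such correlation" = r ≥ −0.3, not "positive").

Two guards handle the small-n statistics of this screen:

* **Dynamic-range requirement.**  With nine samples a Pearson r computed
  against noise falls below −0.3 about 22% of the time (the null r has
  sd ≈ 1/√8), so a correlation over an essentially static promoter is
  uninformative and would both spuriously veto true genes (via the mutant
  condition) and spuriously select null genes.  A correlation therefore
  only counts when the promoter's methylation spans more than
  `min_meth_range` = 0.2 — the same difference that defines a DMR —
  across that genotype's samples.  Below that the gene's methylation is
  treated as static in that genotype: it cannot be negatively correlated
  there.
* **Stage-filter margins.**  The stage-transition filter ("promoter
  methylation up and expression down in siblings, not in the mutant")
  uses margins rather than bare signs, because the sign of a noisy
  zero-mean difference is a coin flip and would flag ~25% of null genes
  in the mutant.  Defaults: methylation increase > 0.1 (half the DMR
  difference threshold) and log2 expression decrease > 0.5 (half the DEG
  fold-change threshold); both configurable.

Genes with fewer than three usable samples in a genotype are excluded and
counted.

## Clone bisulfite summaries

Input is a pre-called clones × CpG binary matrix; read-level alignment
and conversion QC are upstream of scope.  The amplicon summary is
100 × methylated / called entries; missing calls leave both numerator and
denominator.  The per-CpG profile is the column-wise methylated fraction
over called clones; the overall percentage equals the coverage-weighted
mean of the profile.

## The synthetic-data generator

The generator's defaults are the reference scale used throughout the
tests: 2 chromosomes × 1 Mb, geometric inter-CpG gaps with mean 100 bp
(~20k CpGs, 4,000 tiles; no CpG-island structure), Poisson coverage mean
30, 3 replicates × 3 cell types × 2 genotypes, 2,000 genes with 200
methylation-coupled.

Methylation model, per tile: a latent baseline level drawn once from a
Beta with mean 0.8 and concentration 15 (globally high methylation with
realistic tile-to-tile spread), shared across samples; per-sample
replicate noise N(0, 0.03) clipped to [0, 1], so the t-test faces genuine
replicate variance; per-CpG beta jitter (concentration 100) around the
replicate level; counts total ~ Poisson(30), meth ~ Binomial(total, π).

Planted DMRs: 6 × 34 regions, one per coupled-gene promoter (every tile
overlapping the TSS ± 1 kb window; real DMRs span multiple tiles and the
integration needs promoter-wide dynamic range), the four left-over
regions in promoter-free tiles.  Each region carries one of the six
canonical patterns; the affected cell types sit `dmr_delta` = 0.4 below
the pattern's high level (0.85).  The gradual pattern C1 spans 1.5 ×
delta so each of its two stage steps (0.3) stays clearly above the 0.2
DMR threshold while its lowest level (0.25) keeps coupled-gene repression
clearly past the DEG fold-change threshold — planted truth should never
sit on a decision boundary, otherwise "truth" is ill-defined.

Mutant genotype: unplanted tiles are shifted down by 0.15 (floored at 0)
genome-wide; planted regions collapse to a flat low level
(pattern minimum − 0.15) in all cell types, i.e. the methylation dynamics
are abolished, which is the feature of the modelled biology the
integration is designed to detect and yields many more hypo- than
hyper-DMRs in every mutant comparison.

Expression: per-gene log2 baseline ~ Uniform(5, 12); coupled genes in
sibling samples have log2 mean = baseline − 3 × (latent promoter
methylation); coupled genes in mutants and all uncoupled genes sit at
baseline; counts are negative-binomial (gamma–Poisson) with dispersion
0.05.  Coupled genes are therefore de-repressed in the mutant, and the
sibling-only negative correlation is the planted signal.

Ground truth (planted tiles with patterns, true latent tile levels per
group, coupled genes with slopes) is written as sidecar TSVs; the data
files carry no truth.  A fixed seed reproduces every file byte for byte.

What the generator does **not** emulate: CpG islands and other sequence-
driven methylation structure, read-level artefacts (bisulfite conversion
failure, mapping bias, PCR duplicates), SNP-overlapping CpGs, non-CpG
methylation, batch effects, and DMRs with graded or partial effect sizes.
Passing the recovery tests therefore shows the statistics behave as
specified under the declared noise model — not that real data of this
design would yield these rates.  Effect sizes (delta 0.3–0.5) are chosen
relative to the DMR-definition threshold, not measured from real data.

## Problem sizes and tolerances in the test-suite

The acceptance tests run the reference scale (a few seconds each):
null calibration expects the raw p < 0.05 rate in [0.03, 0.07] over
≥ 2,000 tested tiles and ≤ 2 false DMRs of ~4,000 tiles; planted-DMR
recovery expects sensitivity ≥ 0.90 and empirical FDR ≤ 0.10, measured
over planted tiles that are testable under the shared-CpG rule (a tile
with fewer than 3 covered shared CpGs carries no usable signal for any
method — at 100 bp spacing ~12% of tiles, which would otherwise cap
sensitivity around 0.88 for reasons unrelated to the test); global-level
estimation expects ±0.01 at coverage 30; pattern recovery ≥ 95% at noise
sd 0.05; integration expects ≥ 90% of coupled and ≤ 5% of uncoupled genes
selected and stage-filter recall ≥ 0.90 with precision ≥ 0.85 (a handful
of neighbouring genes inherit planted promoter tiles at this gene
density).  Oracle tests compare every elementary statistic (tile and
promoter levels, BH, Fisher/hypergeometric, Pearson, clone percentages)
with independent brute-force implementations on ≥ 100 random fixtures at
numerical precision.

## Known limitations

* The DE engine is a t-test on log counts; for few replicates and low
  counts a negative-binomial model has better power and calibration.
* Tile-level DMRs ignore spatial correlation; no beta-binomial dispersion
  modelling, no HMM segmentation, no merging of adjacent tiles.
* The six-pattern assignment presumes exactly the six canonical shapes;
  profiles far from all centroids are still assigned to the nearest one.
* Enrichment treats tiles as exchangeable units; long-range structure
  (e.g. clustering of planted regions at promoters) is not modelled in
  the null.
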