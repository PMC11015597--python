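# Methods

## Scope and data model

`chromstate` operates on five in-memory types: half-open genomic intervals
(`GenomicInterval`, 0-based BED convention throughout; GFF3 is converted on
read), gene models with strand-aware TSS/TTS and UTR/CDS/intron structure,
a `StateSegmentation` (the genome tiled by labeled state bins, fixed- or
variable-width), stepwise-constant `SignalTrack`s, and `PeakSet`s
(overlapping peaks are merged on load by default, since coverage and
enrichment denominators assume non-redundant regions; a flag preserves raw
peaks). Chromosome-name dialects are normalized through an optional
explicit name map on every reader. Unstranded gene records are treated as
plus-strand with a warning.

## State enrichment

A state bin is a hit when the union of differential regions covers
**strictly more than** `min_bin_coverage` (default 0.5) of its bases; a bin
covered exactly 50% is not a hit. The per-state ratio `hit_i / total_i` is
compared against the global background `Σ hit / Σ total` with a strict
`>` for selection. Significance uses the upper hypergeometric tail
P(X ≥ k) for k hits among `total_i` state bins when `Σ hit` bins are drawn
from `Σ total`; the alternative `tail="point"` returns the point mass
P(X = k), the literal semantics of the spreadsheet function commonly named
in methods sections. A point probability is not a significance measure, so
the tail is the default. Tiers follow the star convention on raw p-values
(no correction by default, matching how such 36-state scans are usually
reported); BH q-values are computed and always included as an extra column.
States absent from a segmentation keep totals 0 and ratio NA — they are
reported, never dropped. Coverage counting is exact: merged regions are
reduced to a piecewise-linear covered-bases prefix function and each bin is
evaluated by two lookups, which the tests check against per-base counting.

The statistic is exposed statsmodels-style: `StateEnrichment(regions,
segmentation, ...)` is the model, `.fit()` returns a
`StateEnrichmentResults` with the per-state table, `selected_states`,
`significant_states(alpha)` and a `summary()` text table.

## Subregion partition and peak→gene assignment

The genome is partitioned into promoter, 5'UTR, coding exon, intron, 3'UTR
and intergenic labels, one per base. Promoter width defaults to 2,000 bp
upstream of the TSS — the same distance as the peak→gene window, a
deliberate single convention since annotation tools differ here. When
labels collide (e.g., a neighbour's promoter over a gene's intron) the
precedence is five_utr > three_utr > coding_exon > intron > promoter >
intergenic: gene-internal annotation beats an adjacent gene's promoter.
Peak distribution is per-base by default (each peak base contributes to
the label it falls on), which is order-independent and matches a
stacked-fraction reading of subregion bar plots; a per-peak majority-vote
mode is available. A gene carries a mark iff any peak overlaps the window
[TSS − 2 kb, TTS] (strand-oriented, clipped at chromosome bounds) by
≥ 1 bp; assignment is deliberately non-exclusive, so one peak can support
two adjacent genes. Gene-set comparisons report shared/exclusive counts
and Jaccard; peak-level set comparison uses any-overlap with a
configurable minimum-fraction option.

## Profiles

All profile values are mean signal density per bin (not sums), so
profiles are comparable across bin widths; the default bin is 50 bp.
Window means are computed from a prefix integral of the step track, so
percent-scaled bins with fractional boundaries are exact rather than
approximated on a base lattice.

* **TSS matrices**: ±1 kb around each TSS, strand-oriented (upstream on
  the left); for minus-strand genes the physical window is mirrored about
  the TSS base. Windows clipped at chromosome ends average only their
  covered bases.
* **Meta-gene profiles**: 1-kb flanks in fixed bins plus the gene body
  resampled into 50 percentile slices, making bodies of different lengths
  comparable. Genes shorter than the number of body bins are skipped with
  a warning (percent bins would be undefined; padding would distort the
  average).
* **Region (PLAD) profiles**: interiors standardized to 3 kb (60 bins)
  with 2-kb fixed flanks, unstranded.
* **Clustering**: k-means (scikit-learn) with k = 8, 10 restarts and a
  fixed seed, on the per-matrix globally z-scored, column-concatenated
  profiles of all marks/conditions — the deeptools-style workflow implied
  by clustered TSS heatmaps. Cluster names C1..Ck are assigned by
  descending size, a stable content-independent convention; empty clusters
  raise a warning. The clustering algorithm and k are configurable since
  no single choice is canonical.

## Expression integration and qPCR math

Fold change is `log2((median_mut + ε)/(median_wt + ε))` over replicate
FPKM medians with pseudocount ε = 0.01 FPKM (recorded on the table object)
for stability at low expression. DEG thresholds are inclusive exactly as
printed: |log2FC| ≥ 0.6 and P ≤ 0.05. Because RNA-seq pipelines vary in
their P-value procedure, the default test is Welch's t on log2(FPKM + 1)
across replicates, and `test="none"` accepts an externally supplied
P-value column so any upstream caller's statistics can be filtered with
the same contract. With noiseless replicates both groups have zero
variance and the t statistic is undefined; that case is mapped to p = 0
when the group means differ and p = 1 otherwise, so planted noiseless
effects are recovered exactly. DEG × mark-change intersection is plain
identifier set algebra with a cross-tab over (direction, mark-change)
pairs.

Relative fold enrichment is 2^−ΔΔCT with ΔΔCT = ΔCT(test) − ΔCT(control)
and ΔCT = CT(target assay) − CT(reference assay) within a sample
(supporting normalization to an internal reference such as 18S/25S). Each
replicate yields its own fold; the report is mean ± sample SD over
replicate folds (SD 0 for a single replicate).

## Synthetic data

The generator exists to give every downstream stage a known ground truth;
one master seed spawns independent per-generator substreams
(`numpy.random.SeedSequence` spawn keys), so adding draws to one generator
never perturbs another and identical configs are bit-identical.

Defaults define the simulation study conditions: 2 chromosomes × 1 Mb
tiled into 200-bp bins (10,000 bins) over 36 states, state frequencies
drawn from a symmetric Dirichlet (α = 5; a literal frequency vector can be
supplied instead, since real segmentations have non-uniform state usage);
400 genes of log-normal length (mean 2 kb) with simple 1–3 exon structures
and 150-bp UTRs; 30 PLADs of log-normal length (mean 10 kb) placed so 2-kb
flanks always exist. Interval placement samples free gaps weighted by
admissible start positions, placing the largest intervals first, so
placement fails only when space is genuinely exhausted.

Differential regions are runs of consecutive bins (default one bin, so the
injected enrichment has an exact multivariate-hypergeometric null); seed
bins in the enriched states are chosen with probability proportional to
`enrichment_odds` (default 8 on state 12, 2,000 regions, matching the
power-analysis conditions; odds 1 gives the calibration null with 1,000
regions). Realized per-state rates are recorded as ground truth.

PLAD tracks put a body mark at 5× background across each domain and a
border mark at 5× over the outer 20% of the domain plus 500 bp beyond each
edge — a fixture convention chosen so the profiler must resolve both an
interior plateau and boundary peaks. Noise is Poisson per 50-bp step with
20 expected events per unit of signal; with noise off, tracks equal the
configured levels exactly.

Expression tables draw baseline FPKM log-normally (median ≈ 10), select
genes for differential expression with probability `de_fraction`, shift
the mutant mean of genes that are both DE-selected and in the mark-loss
set by +2 log2 units, and apply multiplicative replicate noise of 0.2 log2
SD across 3 replicates per condition — an effect/noise regime in which a
median-based filter should recover ≥ 90% of planted genes, as the
end-to-end tests verify. qPCR tables are generated so that the ΔΔCT
analysis recovers specified true folds exactly (optionally with CT noise).

What the generator does **not** emulate: read-level sampling noise and
mappability structure, peak-caller boundary uncertainty, replicate ChIP
variability, correlated state geography (real segmentations have long
same-state runs), and count-based RNA-seq error models. Passing tests
therefore demonstrate the correctness of the interval math, statistics and
recovery logic under controlled conditions — not robustness to every
artifact of real sequencing data.

## Numerical and design notes

* All overlap math is integer/exact; signal integrals are float prefix
  sums (stable at the ≤ 10^6-value scales used here).
* Hypergeometric probabilities come from `scipy.stats.hypergeom`; tests
  validate the upper tail against summed point masses (< 1e-12) and an
  exhaustively enumerable case.
* Validation problem sizes (500 null replicates, 100 power replicates,
  10,000 bins) were chosen as the smallest runs that pin the null
  rejection rate and recovery power tightly; the whole validation suite
  runs in well under a minute per stage on one core.
* Known limitations: BED12 genes carry no UTR information (blocks are
  treated as coding exons); bigWig input is not supported (use bedGraph);
  tracks are assumed depth-normalized upstream; no multiple-testing
  correction is applied to the default tier assignment (q-values are
  provided for users who want it).
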