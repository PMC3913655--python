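# Methods

## Coordinate conventions

All intervals are 0-based half-open, BED dialect on disk. The promoter
of a gene with TSS *t* spans `[t−2200, t+500)` on the + strand and the
mirrored `[t−500, t+2200)` on the − strand; intervals running past the
chromosome start are clipped at 0 with a logged warning. TSS-relative
offsets are strand-aware with upstream negative on both strands; peak
and probe positions are probe-interval midpoints. Genes with several
annotated TSS keep one promoter record per TSS plus an `n_tss` count, so
positional analyses can exclude ambiguous promoters by filtering rather
than by discarding data.

## Binding scores and consensus calls

Each replicate array is normalized by subtracting the median log-ratio
of its control probes (an even control count uses the mean of the two
middle values). The sentence describing this normalization in the
source protocol is ambiguous about which array type it applies to, so
the step is a flag (`normalize={control-median,none}`); with no control
probes present the fallback to the all-probe median must be requested
explicitly.

Smoothing is a 400-bp windowed median centred on each probe: the window
membership is by probe midpoint, boundary-inclusive, includes the probe
itself (so an isolated probe smooths to its own value), never crosses a
chromosome, and excludes control probes. Input must already be sorted
by (chromosome, midpoint); unsorted input is an error rather than a
silent reorder, because silent sorting can mask upstream bookkeeping
bugs. The per-promoter score (Max400) is the maximum smoothed value over
the promoter's probes; exact ties are broken toward the probe nearest
the TSS, then the smaller coordinate. Per replicate, the top-k promoters
(k = 500 by default; ties at the boundary break by score then promoter
id) form the replicate's candidate list, and a promoter is a direct
target when it appears in at least m = 2 of the n = 3 lists.

Two structural properties of this scheme are worth knowing:

* **Consensus precision is bounded by chance rank overlap.** Unbound
  promoters' scores are exchangeable across replicates, so if the
  top-k list has f free slots beyond the truly bound set, a fraction
  f/U of the U unbound promoters enters each list and an expected
  U·3(f/U)² of them pass the 2-of-3 rule. At k twice the bound count
  this caps precision near 0.86 however strong the enrichment; raising
  m to 3 or shrinking k restores precision at the usual cost in recall.
* **Peak positions have window-scale resolution and a TSS-ward lean.**
  Adjacent probes' windows share most of their members, so for a
  symmetric enrichment bump the median-smoothed score is flat (often
  exactly tied) across the three probes around the summit; the
  nearest-TSS tie rule then prefers the downstream edge of that
  plateau. Peak positions are therefore only localized to about the
  window width, and single-call positions lean up to one probe spacing
  toward the TSS.

## Peak localization

Per promoter and replicate the peak is the Max400 probe midpoint. A
cross-replicate peak call requires a group of ≥ m positions pairwise
within a tolerance (default one probe spacing, 100 bp, since positions
are probe-quantized); the call position is the median of the agreeing
group, and its support the group size. When several maximal groups tie,
the leftmost is taken (deterministic; which of two one-spacing-apart
pairs is "the" peak is genuinely ambiguous). Peak sequences are the
consensus peak probe's own interval extracted from the genome FASTA,
reverse-complemented for − strand promoters.

The TSS-offset histogram uses only single-TSS promoters (multi-TSS
promoters are tallied separately) and, following the resolution argument
above, bins offsets at the smoothing-window width (400 bp) by default —
narrower bins would overstate the method's positional precision. The
average binding curve (replicate-mean smoothed intensity by offset bin)
uses 100-bp bins since it aggregates probes, not peak calls.

## Expression analysis

Columns are quantile normalized: every column's sorted values are
replaced by the across-column mean of order statistics; ties within a
column receive the mean of the normalized values their positions would
have received (this makes the operation idempotent up to the tie
policy).

Sample QC mirrors, mechanically, the pairs-plot screening used for
small two-arm designs: each silenced sample's per-gene log-ratio
against the control-arm mean is correlated with its peers'; the sample
with the lowest mean pairwise correlation is flagged when that mean
falls below 0.5 or trails the arm mean by more than 0.2, and the rule
repeats on the remainder. Flagging is greedy/iterative because with
three silenced samples one corrupted sample drags its peers' means down
with it; a single pass would false-flag clean samples. Flagged samples
are excluded from differential expression with a logged record;
differential expression refuses to run with fewer than two samples per
arm.

The default per-gene test is a pooled-variance t with the per-gene SD
moderated by adding the median pooled SD — with 2–3 samples per arm raw
per-gene variances are unstable denominators, and the shift keeps
zero-variance genes finite while shrinking small-variance genes toward
the typical noise level. The alternative (`method="rank"`) is the exact
permutation of arm labels on the mean difference (10 partitions at
2 vs 3, so the p-grid is k/10). No significance threshold is hard-coded:
the published analysis this mirrors never states the criterion behind
its significant-gene count, so significance is an explicit parameter
and ranked top-N lists are the primary interface. Ranking is by
statistic by default (fold-change ranking is a flag), with
deterministic (statistic, gene id) tie-breaks.

## Integration

The collective-shift test compares knockdown log-ratios (mean silenced −
mean control per gene) of the direct set against all other measured
genes. The primary statistic is the two-sided Wilcoxon rank-sum —
appropriate for comparing two groups of per-gene changes without
distributional assumptions — with Welch t and KS reported alongside;
direction is the sign of the median difference. The overlay table pairs
each gene's baseline expression (control-arm mean as the untreated
proxy, rank-transformed by default) with its knockdown response and a
direct-target flag. The target partition keeps both routes first-class:
the strict intersection with DE-significant genes (which can
legitimately be empty under a stringent criterion) and the relaxed
intersection with the expanded top-N up/down lists.

## Copy-number stage

The caller is deliberately minimal: probes are binned (10 kb default),
each bin's median log2 ratio is thresholded (≤ −1.2 homozygous loss,
≤ −0.3 hemizygous loss, ≥ +0.3 gain), and adjacent same-state bins merge
into segments. No smoothing or minimum-length filter is applied, so
isolated noise bins can appear as short spurious segments; the
downstream question — which region do losses share — is robust to them,
but the commonly-deleted-region support can slightly exceed the true
number of deleted samples. Samples are clustered by average linkage on
the Hamming distance of their bin-state vectors (note a homozygous
deletion differs from a hemizygous one at every deleted bin under this
distance, so zygosity separates before deletion status). The commonly
deleted region is found by sweep-line interval stabbing over per-sample
unions of loss segments; ties on support resolve to the leftmost
interval.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analysis
assumes, with defaults fixed at the study conditions:

| parameter | default | rationale |
|---|---|---|
| genes / bound | 2000 / 108 | desk-scale promoter set with the reference bound-set size |
| probe spacing / span | 100 bp over (−2200, +500) | the tiling design; 27 probes per promoter |
| probe lengths | even, 50–64 bp | within the 50–75 bp design; even lengths keep midpoints on the offset grid; upper end matches reported peak-sequence lengths |
| replicates | 3 | the experimental design |
| background noise SD | 0.25 log2 | typical tiling-array probe noise |
| peak amplitude / center / width | 1.0 log2 at −500 bp, SD 300 bp | 4-sigma enrichment centred at the reported modal offset; width of the order of the sheared-chromatin fragments (200–1000 bp) |
| per-array offset SD | 0.1 | the global bias control-median normalization removes |
| expression arms | 3 silenced + 3 control, noise SD 0.25 | the experimental design |
| knockdown effect | −1.0 log2 on bound genes | activator model: silencing lowers direct targets |
| indirect responders | 5% of unbound genes, random sign | secondary regulatory effects; they also give silenced replicates realistic shared structure |
| bad sample | off; noise ×5 when on | a corrupted replicate for QC exercises |
| CNA | 22 samples, 10 deletions sharing a 400-kb core, ≤300-kb endpoint extensions, noise SD 0.2 | deletions much larger than their endpoint variability, sharing a gene-cluster-scale core |

Truth sets (bound genes, indirect effects, corrupted sample, deletion
intervals) are returned beside the data and consumed only by tests.

Not emulated: probe sequence effects (GC/Tm-dependent affinities shared
across replicates — these would correlate replicate noise and lower
consensus precision further), spatial autocorrelation of array noise,
probe-level outliers, cross-hybridization, batch structure beyond the
global per-array offset, and gene–gene expression correlation. Passing
tests therefore demonstrate correctness of the computations and
recovery under the assumed noise model, not robustness to every
artifact of physical arrays.

## Problem sizes and numerical choices

Tests and the acceptance script run the full pipeline at 2000 promoters
× 27 probes × 3 replicates and 20 seeds for stochastic properties, the
scale at which the bound-set size matches its reference value while a
seed completes in seconds. Medians of even counts are the mean of the
two middle values throughout (the numpy convention). All determinism
flows from a single integer seed through `numpy.random.default_rng`;
equal-score and equal-size ties everywhere break by explicit
deterministic keys (documented per operation above) so outputs are
byte-reproducible across runs and platforms.
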