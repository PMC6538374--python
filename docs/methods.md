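# Methods

This note records the models, conventions and numerical choices behind
`peakladder`, in the order a pipeline run encounters them, together with
the design decisions that were genuinely open and the limitations a user
should know about.

## Coordinates and interval semantics

All intervals are 0-based half-open `[start, end)` on named chromosomes
(the BED dialect). Two intervals overlap iff they share at least one base;
bookended intervals (`a.end == b.start`) do not overlap, and interval
merging keeps them separate. No minimum-overlap-fraction option exists:
every overlap test in the pipeline is a bare intersection. Strand is
ignored in all overlap computations (ATAC and ChIP peaks are unstranded);
it is used only to resolve a gene's TSS from a gene body (`start` on `+`,
`end - 1` on `-`, the 5' base in half-open coordinates) and to orient
metaprofiles. Gene tables may declare `coordinate_system=1` to mark 1-based
TSS positions, which are shifted on read rather than guessed.

The overlap/merge/nearest engine runs on per-chromosome sorted arrays
(binary search against a merged feature list); the test suite checks it
against brute-force all-pairs and per-base-occupancy oracles on hundreds of
randomized instances. Closest-gene distance is 0 when a TSS lies inside
the peak and otherwise the distance from the TSS to the nearer peak edge;
ties break to the lexicographically smallest `gene_id` so results are
deterministic.

## Peak post-processing

Four steps, in pipeline order:

1. **High-depth exclusion.** The top fraction (default 0.1%) of peaks by
   aligned-read depth are removed per input peak set, before merging;
   exactly `floor(fraction * n)` peaks are removed, so nothing is removed
   when `n < 1/fraction`. Depth ties break by (chrom, start), removing the
   later-sorted peak first. This models the removal of regions of
   exceptionally high artifactual depth.
2. **Merging.** Peak sets from all conditions are unioned into the
   "considered regions" — the statistical universe for all peak-level
   tests. Only strictly overlapping intervals coalesce.
3. **Max-group-mean (mgm) filter.** A region is kept only if its largest
   per-condition mean read count strictly exceeds a floor (presets: 8 reads
   for the steady-state regime, 32 for the neural-induction regime) —
   regions whose signal is indistinguishable from background in every
   condition carry no usable differential information.
4. **Differential call.** With thresholds `(q_max, fc_min)`: higher
   accessibility (HA) means `q < q_max` and linear fold change
   `>= fc_min`; lower accessibility (LA) means `q < q_max` and the
   inverse-contrast ratio `>= fc_min`. Fold changes may be encoded either
   as plain ratios or in the signed convention common in published tables
   (-7.9 for 7.9-fold down); both are accepted. The two published regimes
   are exposed as presets: `steady_state` (q < 0.05, FC > 1.5, mgm 8) and
   `neural` (q < 0.01, FC > 2, mgm 32). The source analyses state the
   neural fold-change threshold inconsistently (linear 2 in one place,
   log2 2 = linear 4 in another); the preset uses linear 2 and the
   threshold is an explicit knob rather than an assumption.

Computing q-values and fold changes from raw counts is out of scope; the
package thresholds an existing statistics table.

## Hypergeometric tails

`hypergeom_upper_tail` evaluates `P(X >= q)` (inclusive, the standard
enrichment convention and the default) or `P(X > q)` (exclusive — the
literal behaviour of R's `phyper(..., lower.tail = FALSE)`), through the
survival function of `scipy.stats.hypergeom`, which works in log space.
The suite verifies it against two independent routes: exhaustive
enumeration of all draws for every universe of at most 14 items, and a
log-factorial closed form on 500 random cases up to universe 500 at
relative error 1e-10. Before plotting, p-values are floored at 1e-300 so
`-log10 p` stays finite on saturated tests.

## The distance ladder and its null

For each distance `d` in a grid, every target peak is widened by radius
`d` (a "20 kb range" means within 20 kb of the peak edge; a
`range_mode="total_width"` alternative widens by `d/2` since the published
phrasing does not fully disambiguate the two readings), widened ranges are
clipped to chromosome ends and unioned, and genes are counted once however
many ranges cover them — sampling without replacement requires distinct
items. The default grid runs in 5 kb steps to 100 kb, 25 kb steps to
500 kb, then 100 kb steps to 2 Mb, preserving the documented 5 kb start
and 2 Mb endpoint while keeping the far tail cheap; a uniform grid is a
one-liner if wanted.

The null model draws random peak subsets from the considered-peak
universe, **matched in number and width**: bin edges are the deciles of the
target set's own widths, and each random set draws the target's per-bin
counts without replacement from universe peaks in the same width bin,
borrowing from the nearest adjacent bin (with a logged warning) when a bin
runs short. Decile binning is scale-free and reproducible; the matching
deliberately stops at width and number — GC- or signal-matched nulls are
out of scope. Per distance, the (5%, 50%, 95%) quantiles of `-log10 p`
across random sets (linear-interpolation, type-7 quantiles — the numpy
default) form the envelope reported alongside the observed curve. The
default is 1000 random sets, mirroring the published procedure; the tests
use 100. No multiple-testing correction is applied across distances or
feature sets: raw p-values are reported, as in the source analyses.

## Overlap and composition tests

**Region-overlap enrichment**: `q` = differential peaks overlapping >= 1
feature, `m` = universe peaks overlapping, `n` = universe peaks not
overlapping, `k` = size of the differential set; the differential set must
be coordinate-identical to a subset of the universe, and a mismatch is an
error rather than a silent re-universe. `feature_centric` mode additionally
reports how many features are hit (for statements like "127/684 regions").

**TSS-window enrichment** is gene-centric: a gene's window is
`[tss - w, tss + w + 1)` (symmetric and closed around the TSS, default
w = 2.5 kb), and the counts are windows hitting >= 1 feature among all
genes versus among labelled genes.

**Composition** tallies chromatin classes (bivalent, H3K4me3-only,
H3K27me3-only, neither, plus an explicit `unclassified` bucket for genes
without a class) over a gene list; every class is reported even at zero
count and fractions sum to one. The closest-gene variant maps each peak to
its nearest gene and deduplicates before tallying.

## Signal normalization and summarization

Median equalization finds per-condition factors that equalize median read
counts over high-signal regions: (1) each region's cross-condition mean;
(2) retain regions whose mean strictly exceeds the median of those means
(ties at the median excluded — the literal reading of "above the median");
(3) reference = geometric mean of per-condition medians over retained
regions; (4) `factor_c = reference / median_c`. Which signal the retention
filter should use was ambiguous in the source; filtering on the
cross-condition mean is symmetric in conditions, and the geometric-mean
reference makes the factors invariant to condition order. Applying the
factors equalizes retained-region medians to the reference within 1e-9
relative error by construction.

Per-region normalized counts are `sum(value x covered bases) x factor`
over bedGraph segments, with uncovered bases contributing zero and a
missing chromosome yielding zero with a warning rather than an error.
Metaprofiles split each region into `n_bins` near-equal bins — remainder
bases go to the leftmost bins, so profiles are bit-reproducible — average
per-base signal within bins, reverse minus-strand regions per-base before
binning (bin 0 is always the 5' end), and average unweighted across
regions. Scaled-region binning (not fixed-width anchors) was chosen
because the regions of interest (super-enhancers) vary five-fold in width.
Statistical calling of differentially transcribed regions from these
counts is out of scope — only the counting layer is implemented.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, on
a genome scaled to 2 x 20 Mb so that a full 1000-set resampling run
finishes in seconds. Defaults, with units and rationale:

- **Genes**: 1000, uniform with >= 5 kb TSS spacing, random strand — gene
  density (25/Mb) comparable to gene-rich mammalian regions.
- **Peaks**: 5000, log-normal widths (median 400 bp, log-sd 0.5, the shape
  of typical ATAC peak-width distributions), 30% placed promoter-proximal
  (Gaussian offset, sd 2 kb) and the rest uniform; the universe is thinned
  to be non-overlapping, as merged peak calls are.
- **Differential peaks**: 300, split evenly HA/LA, with q drawn in
  [1e-8, 6e-3] and fold-change magnitudes >= 2, so they pass both threshold
  presets; non-differential peaks draw q in [0.2, 1] and |log2 ratio|
  around 0.2, so they pass neither.
- **Planted linkage**: each differential peak, with probability pi = 0.6,
  labels one gene within D = 50 kb concordantly (HA -> up, LA -> down);
  concordance is planted because the analysis pairs gained accessibility
  with upregulation. Background genes are labelled differential at rate
  0.02 with random direction. The manifest records every planted pair and
  distance.
- **Chromatin classes**: bivalent at 0.18 baseline versus 0.29 among
  differential genes (the published composition contrast), remainder split
  k4-only/k27-only/neither at 0.50/0.07/0.25 of the residual mass.
- **Counts**: per-condition group means are means of 2 negative-binomial
  replicates with mean = 0.5 reads/bp x width x s_c and dispersion 0.2.
  Two replicates matches the source design; 0.5 reads/bp puts the median
  considered region near 200 reads, well above the published mgm floors
  (which are noise floors, not typical values) — at much shallower depth,
  integer-count granularity alone would dominate median-ratio recovery.
  Planted condition scales default to {control: 1.0, kd: 1.5}; a
  `noiseless` mode emits the exact means for exactness tests.
- **Artifacts**: 3 regions of 2 kb at ~100x the maximum peak depth,
  mimicking alignment pile-ups; they are the depth outliers by
  construction, so high-depth exclusion removes them first.
- **Features**: 30 super-enhancers (10-50 kb, centred on random TSS), 500
  enhancers (1 kb) and 2000 TF sites (200 bp) placed uniformly.
- **Tracks**: per-condition bedGraph with per-base value = group mean /
  width over each region — sufficient for the counting and profiling
  layers, which are linear in the track.

Everything derives from a single integer seed; identical configs produce
byte-identical bundles. `truth_check` verifies the bundle against its
manifest: chromosome consistency, exact recovery of the planted
differential sets by thresholding, artifacts being the top depth outliers,
DE-label tallies, and (noiseless mode) exact factor recovery.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: read-level structure (fragment sizes, Tn5 bias,
duplicates), GC and mappability covariates, correlated peak-peak structure
beyond promoter clustering, distance-dependent decay of regulatory
linkage (the planted link is uniform within D), differential counts that
actually differ between condition tracks, and realistic chromosome-scale
heterogeneity. Calibration and recovery results on synthetic bundles
validate the statistical machinery, not the biology of any particular
dataset.

## Validation results computed by the suite

The acceptance tests (tests/test_acceptance.py) compute, at run time: the
worked-example probability from printed counts under both tail
conventions; exhaustive-enumeration and closed-form agreement of the
hypergeometric tail; the 95%-envelope exceedance rate over 200 no-linkage
bundles at the 50 kb distance (expected ~5%); planted-linkage recovery
(observed curve above the 95% envelope at every distance from 10 to 50 kb)
over 50 seeds; planted-factor recovery in noiseless (1e-9) and noisy (1%)
regimes; and the filtering determinism rules. Problem sizes (5000-peak
bundles, 100-set nulls, 50-200 replicates) are the package's chosen desk
scale; all are configurable upward.

One caveat is inherited from the source rather than the implementation:
the printed worked-example probability (7.6e-5) is not exactly
reproducible from the printed counts (they yield 1.2-1.7e-4 depending on
tail convention); the printed percentages imply the original gene universe
differed slightly from the quoted 17,462. The package reports what the
stated counts give and does not force agreement.
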