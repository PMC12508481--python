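# Methods

## Coordinate model

All coordinates are 0-based, half-open (BED convention); GTF input (1-based,
closed) is converted at the parser boundary so a single convention holds
everywhere internally. The TSS anchor of a gene is a 1 bp interval at the
gene start (+ strand) or `end − 1` (− strand). Binned tracks hold one float
array per chromosome at a fixed bin size; bin *i* covers
`[i·bin, (i+1)·bin)`. Missing data is explicit (NaN), and every windowed
mean ignores missing bins — this matters for RFD, which is undefined where
Okazaki-fragment coverage is zero. bedGraph is the on-disk track format;
runs of identical adjacent values are merged on write and re-expanded on
read, so track round-trips are exact.

## Sequence statistics

**GC content and skew.** `gc_fraction = (G+C)/(A+C+G+T)` and
`gc_skew = (G−C)/(G+C)`, both counting unambiguous bases only; a window
with no G or C has undefined (missing) skew rather than raising. Positive
skew on the non-template strand marks the G-rich displaced strand that
stabilizes R-loops.

**G4 propensity.** Per-base run scoring: each base in a maximal run of *k*
consecutive G scores `+min(k, 4)`, C runs score `−min(k, 4)`, everything
else 0; a window's score is the mean of its per-base scores, so it is
bounded by ±4. The published tool the field uses for this statistic applies
exactly this rule; it is reimplemented here (and pinned against an
independently written brute-force scorer in the tests) to remove the
external-tool dependency. Ambiguous bases score 0.

**Profiles.** Skew profiles scan ±5 kb around each TSS with 200 bp windows
sliding 1 bp; G4 profiles scan ±1 kb with 25 bp windows. Sequences are taken
in the gene's reading direction (− strand anchors are reverse-complemented,
mirroring offsets), scored per window, then averaged per offset across
anchors with missing-aware counts. Anchors lacking full flank room are
skipped and counted rather than clipped, keeping every offset's *n*
interpretable. Across anchors the G4 profile averages |window score| by
default — a quadruplex can form on either strand — with a signed mode behind
a flag. Window scores below the reporting threshold (default 0) are floored
to zero.

## Peak annotation and bound-TSS selection

Peaks are classified by their midpoint with fixed priority
promoter > exon > intron > downstream > intergenic, which makes the
categories a partition (pie-chart compatible). "Promoter" means |signed
distance to the nearest TSS| ≤ 1 kb (the promoter window is a logged,
required parameter); "downstream" means within 3 kb past the gene's 3' end,
strand-aware. UTRs are collapsed into exon. The signed TSS distance is
negative upstream in the gene's reading direction, ties broken by absolute
distance then leftmost TSS. A TSS counts as factor-bound when its nearest
peak *edge* is strictly closer than 3 kb.

## GC-matched control TSS sets

Controls are drawn by exact per-histogram-bin stratification: GC% is
computed over ±1 kb of each TSS (GC is strand-symmetric, so no reverse
complement; windows are clipped at chromosome ends), binned at width 0.01,
and each control set replicates the bound set's bin counts exactly.
Candidates at a bound TSS position or within 3 kb of any peak edge are
ineligible — "unbound" mirrors the bound definition. Sampling is without
replacement from a deterministically ordered pool under a fixed seed, and
the two default control sets are disjoint (flag-controlled). Exact
stratification was chosen over nearest-neighbor GC pairing because it is
auditable: per-bin identity makes the binned GC distributions of bound and
control sets equal at every bin boundary, an invariant the tests assert
directly. A bin with too few eligible candidates raises an error naming the
bin and shortfall; the fixtures therefore use candidate pools an order of
magnitude larger than the bound set, as a genome-scale annotation provides.

## Signal metaprofiles

The reference-point aggregation takes, per anchor, the track over
±flank (default 3 kb) resampled to an output grid (default 50 bp) by
overlap-weighted mean of the fine bins each output cell covers; a cell is
missing only if every covered fine bin is missing. Rows of − strand anchors
are reversed so offsets read in gene direction. The summary profile is the
missing-aware column mean with per-offset counts. Scale-regions mode is not
implemented.

## Replication fork directionality and TRC sites

RFD per bin is `(C − W)/(C + W)` from Watson/Crick Okazaki-fragment counts
after an optional centered moving average of both strands (half-width 2
bins by default); bins whose smoothed coverage falls below `min_total = 10`
are missing. The sign convention is positive = rightward-moving forks
(Crick excess). Default OK-seq bin size is 1 kb; all three values are
explicit knobs chosen so that sampling noise at realistic depth does not
fragment plateau regions.

High-|RFD| regions are maximal runs of bins strictly beyond ±0.75,
bridging at most one interior sub-threshold or missing bin, never a bin
qualifying for the opposite sign, and requiring at least five qualifying
bins. Run calling replaces the HMM segmentation used upstream of this
filter in published pipelines: the objects consumed downstream are defined
purely by the |RFD| > 0.75 criterion, so explicit thresholded runs (with
`min_region_bins` and `merge_gap_bins` as parameters) reproduce the filter
without a state-decoding dependency.

Genes must be fully contained in a single region (containment, not
overlap — the literal reading; each kept gene carries the region's sign).
Gene bodies are intersected with R-loop (DRIPc) peaks strand-agnostically;
for a gene with at least one overlap, the overlap span runs from the
leftmost overlap start to the rightmost overlap end across all intersecting
peaks — the deterministic, symmetric reading for multi-peak genes. The TRC
window is the span center ± 10 kb; controls are 20 kb windows centered 1 Mb
up- and downstream. Sites whose window or either control would leave the
chromosome are dropped (not clipped) so control means stay comparable
across sites. Orientation is head-on when transcription opposes the
predominant fork direction ((+ gene, − region) or (− gene, + region)),
co-directional otherwise.

## Enrichment scoring

Coverage is normalized to RPKM, `count / ((bin/1000)·(total/10⁶))`, at
100 bp bins (CPM available), and replicates are averaged element-wise with
missing bins excluded per position. Per site,
`ratio = (TRC mean + pc) / (½(ctrl_up + ctrl_down) + pc)` with pseudocount
0.01 guarding zero-coverage windows; the factor summary is
`log2(mean over sites of ratio)`. The order of averaging and log is not
dictated by the ratio definition alone; this package fixes
mean-then-log (the alternative, mean of per-site log2 ratios, is available
behind a flag and both are recorded in the run manifest). The ratio is
scale-invariant up to the pseudocount, antisymmetric under swapping window
and controls in the pc→0 limit, and centered on 0 for a flat track — all
asserted in the tests. No input/no-antibody subtraction is applied;
negative-control datasets are scored as factors and compared.

## Synthetic data

The generators are pure functions of a seeded config and return truth
records sufficient to score recovery without re-deriving ground truth.

* **Genome**: i.i.d. bases at a background GC fraction (default 0.45).
  Planted promoter skew re-draws G/C bases over the first 1 kb downstream
  of designated TSSs with `P(G | G∨C) = (1 + a)/2` on the non-template
  strand (default amplitude a = 0.3, mirrored for − genes) — this preserves
  GC content exactly, so skew planting cannot leak into GC matching. Short
  CGG tracts (n < 10 repeats by default) are written immediately downstream
  of designated TSSs on the gene strand.
* **Annotation**: non-overlapping genes (default 60 per Mb-scale
  chromosome, 5–15 kb, ≥ 1 kb apart, random strands) packed with an end
  margin so profile windows fit.
* **OK-seq**: the true RFD is a step function of the planted origins — +1
  right of an origin up to the midpoint to the next, −1 beyond — with an
  optional linear ramp at transitions (default width 0). Per bin,
  total ~ Poisson(depth, default 200) and Crick ~ Binomial(total,
  (1 + r)/2). A full replication-kinetics simulation is deliberately out of
  scope: the pipeline consumes only RFD-level structure, so plateaus above
  the calling threshold are what the caller needs to see.
* **ChIP**: per-bin counts ~ Poisson(background · fold), fold planted per
  site (background 50 reads per 100 bp bin by default). Noise is Poisson
  without overdispersion; that suffices to exercise the ratio estimator's
  tolerances, and a negative-binomial flag is reserved for later.
* **DRIPc**: a seeded gene subset (default half) receives one peak of
  0.5–2 kb placed inside the gene body.

What the generators do **not** emulate: mappability and blacklist
structure, fragment-length and GC bias, copy-number variation, replication
timing gradients between origins, overdispersed ChIP noise, and peak-caller
artifacts. Passing tests therefore demonstrate that the estimators recover
the structure they are defined on, not that real-data preprocessing is
handled; preprocessing (alignment, deduplication, peak calling) is outside
the package by design, which consumes peaks and tracks as given.

## Problem sizes and numerical choices

The test suite and acceptance script run on deliberately compact instances:
1000 random 100-mers for exact scoring equivalence; a 1 Mb chromosome at
1 kb bins and 200 reads/bin for RFD recovery (observed mean absolute error
≈ 0.007, asserted ≤ 0.05); a 5 Mb two-origin chromosome with 30 plateau
genes and DRIPc fraction 0.5 for exact TRC recovery; 50 sites spaced
2.03 Mb (so controls never touch a neighboring planted window) for
enrichment recovery of folds {1, 2, 4, 8} within ±0.15 log2 units; and an
8 Mb, 600-gene genome with 30 designated bound promoters for the
planted-skew pipeline. Tie-breaks (nearest-TSS, leftmost), strict vs
non-strict thresholds (`< 3 kb` bound distance, `> 0.75` RFD), and the
floor-binning rule for GC stratification are fixed and documented at their
definitions; degenerate inputs (empty sets, all-missing windows,
zero-coverage totals) raise typed errors or propagate missing values per
the contracts above.

## Known limitations

* Interval search is linear per chromosome; adequate for peak sets up to
  ~10⁴ intervals, not tuned for dense genome-wide catalogs.
* The G4 statistic is a propensity score, not a thermodynamic or
  structure-resolved prediction; RNA G4s and inter-molecular topologies are
  out of scope.
* TRC orientation uses the region's dominant RFD sign; within-region fork
  heterogeneity is not modeled.
* Enrichment is descriptive (no across-factor statistical test), matching
  the window-vs-control ratio it implements.
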