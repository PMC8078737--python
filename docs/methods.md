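# Methods

## Coordinate model and oriented windows

All coordinates are 0-based half-open (BED convention). An anchored region
is a gene body `[gene_start, gene_end)` with an anchor: a replication origin
inside the body (`origin_in_gene_body`), the body midpoint
(`gene_body_center`), or an arbitrary genomic point (`random`). Anchors are
snapped down to the containing bin boundary so every window tiles exactly
`2·half_width / bin_width` bins (240 for the default 24-kb window of 100-nt
bins); the binning phase of the underlying data is otherwise unknowable, and
floor-snapping keeps window construction deterministic and grid-aligned.

Windows are expressed in transcription-oriented offsets: for a minus-strand
gene the genomic bin list is reversed before aggregation, so negative
offsets always point upstream of the anchor in the transcription direction.
In this frame the head-on (HO) collision sub-region is `[-6000, 0)` and the
co-directional (CD) sub-region `[0, +6000)`; their union is the ±6-kb
quantification window. Random regions carry '+' strand by construction — no
transcription direction exists there, so no inversion is meaningful.

Windows that would overrun a chromosome end are dropped from aggregation and
counted, not zero-padded: padding would bias edge bins of the mean profile
toward zero. Random windows are drawn uniformly over the positions where
the full window fits, with the chromosome chosen proportionally to its
usable length; windows may overlap one another, and the reported genome
coverage of a random-window set is the nominal overlap-ignoring span
`n·width / genome_length` (50,000 windows of 24 kb on a 3.10-Gb genome span
38.8%, "approximately 40%").

## Signal model

The signal of a 100-nt bin is a mapped read count. Each read is assigned to
exactly one bin — the one holding its strand-aware 5′ end (start for '+',
`end − 1` for '−'). Single-point assignment makes count conservation exact
(track total = reads binned) and binning linear in the read set; with
~100-nt reads and 100-nt bins it is nearly indistinguishable from
overlap-proportional counting, but the choice is recorded here rather than
inferred. Duplicate removal is assumed done upstream; an exact-interval
`dedup` switch exists for synthetic data.

Normalization multiplies every bin by `10⁷ / library_size`, where
`library_size` defaults to the number of reads ingested and can be
overridden when a file holds only part of the mapped library. Normalizing
twice is an error by design: the transform is a change of scale, not a
projection, and silently accepting a second application would corrupt
contingency tables downstream.

## Metaprofiles and bootstrap

The metaprofile matrix holds one row per surviving region and one column per
oriented bin. Summaries are column-wise means or medians; medians use
lower-interpolation so every reported value is an observed one and reruns
are deterministic. Bootstrap bands resample **regions** (rows) with
replacement — regions are the independent units of the design — 10,000
times by default, and report the 2.5/97.5 percentile interval of the
statistic. Mean bootstraps use multinomial resampling weights (a matrix
product instead of explicit indexing); median bootstraps are chunked to
bound memory. A single-region profile yields a degenerate band with a
warning. Per-region sub-window averages are arithmetic means over the bins
whose offsets fall in the sub-window; their ECDF is the right-continuous
step function with ties merged.

## Enrichment testing

The published analysis reports Fisher exact tests "by normalized
read-counts mapped to 12 kb or 6 kb window" without defining the table
cells. The construction adopted here is the simplest reading: for each
sample, cell `a` is the normalized count summed over all regions'
sub-windows, rounded half-to-even (Fisher requires integers; banker's
rounding is bias-free), and cell `b` the remainder of the 10M-scaled
library, with `c`/`d` the control analogues. This makes margins comparable
across samples and isolates the choice in one function so alternative
constructions (per-region tables, raw counts) can be swapped. The two-sided
p-value follows the minimum-likelihood rule (SciPy's convention, matched
exactly by a full-support hypergeometric enumeration oracle in the tests);
the odds ratio is the sample estimate `ad/bc`, NaN when undefined. A zero
margin gives p = 1 and an undefined odds ratio. Bonferroni correction uses
`m` = all tests in one invocation batch (samples × sub-windows), the most
conservative reading of an unspecified family.

A statistical caveat this package makes explicit: treating the scaled
remainder `10⁷ − a` as a fixed margin is only calibrated when (i) library
sizes are at or above the 10M normalization target, so scaling never
inflates counts beyond their sampling variance, and (ii) the quantified
windows hold a small fraction of the library, so the finite-population
variance deflation of the hypergeometric null is negligible. Both hold for
real duplicate-removed DRIP-seq libraries (tens of millions of reads;
727 windows × 12 kb ≈ 0.3% of hg19) and for the simulator defaults; the
null-calibration test verifies the type-I error directly.

## Synthetic data

The generator emulates the real inputs' structure: a study-scale region
table (727 origin-class + 484 center-class gene bodies by default), gene
lengths uniform on 14–30 kb (so ±6-kb sub-windows always fit inside the
body), strands Bernoulli(½), non-overlapping uniform placement (sorted
uniform gaps over the slack space), and origin anchors uniform in the gene
interior at least 6 kb from both ends. Per-bin read counts are Poisson with
background rate λ = 2 reads/bin by default, multiplied by `fold_ho` /
`fold_cd` in the case sample's oriented HO/CD sub-windows of origin-class
regions (piecewise-constant enrichment: the block structure the statistics
assume). The default genome (2 × 250 Mb) puts realized library sizes at the
10M-read scale of the normalization target, matching real duplicate-removed
libraries and the calibration requirement above. An optional gamma-mixing
overdispersion knob provides negative-binomial noise but is off by default
so that every expectation stays closed-form: the expected normalized window
average is `λ · fold · 10⁷ / E[library]`, which the truth object computes
for oracle tests. Configured library sizes are imposed by multinomial
thinning/inflation of the realized counts.

Reads can be materialized as 100-nt '+'-strand BED intervals whose 5′ ends
lie uniformly within their generating bin; binning such a read set
reproduces the generating track exactly, which the tests exploit as a
round-trip identity. What the simulator does **not** model: mappability and
GC structure, fragment-length variation, duplicate structure, peaky R-loop
shapes, or correlated noise between neighbouring bins. Passing tests
therefore demonstrate correctness of the pipeline's arithmetic and
calibration of its statistics under the assumed noise model, not robustness
to every artefact of real sequencing data.

## Problem sizes and numerical choices

The test suite and acceptance script scale the study conditions to
desk-size problems chosen once: null calibration uses 200 replicates of 100
origin regions on a 100-Mb chromosome at λ = 10 (library ≈ 10M, in-window
fraction ≈ 0.6%); the power/contrast study uses the full default
conditions (727 regions, λ = 2, fold 2) over 12 simulation seeds; fold
recovery uses λ = 5 and 200 regions over 10 seeds, where the only bias is
the ~1% library-size shift caused by the injected reads themselves. Null
rejection rates are compared against the nominal 5% with a 2.33-σ binomial
Monte-Carlo allowance. Exact-agreement oracle tests use tolerance 1e-12
(Fisher enumeration) or bitwise equality (binning, aggregation,
orientation). Bootstrap means at n_boot = 10,000 run in ~1 s for 727 × 240
matrices; medians are used at reduced n_boot in routine runs.

## Known limitations

- The contingency-table construction is one defensible reading of an
  under-specified published procedure; absolute p-values depend on it (and
  on the unstated Bonferroni family size), so cross-study comparisons
  should treat the HO/CD *contrast*, not the absolute p, as the result.
- Summed-across-regions testing answers "is the window set as a whole
  enriched"; it does not localize enrichment to particular genes.
- ECDFs and window averages use per-region means of normalized counts;
  per-region sums would weight long windows identically but scale
  differently.
- Library-scale normalization introduces a composition effect: when one
  window class is genuinely enriched in a sample, every other window of
  that sample is scaled slightly *down* relative to the control, so
  unenriched windows can show a small systematic depletion (odds ratio
  marginally below 1). With a 2-fold HO enrichment over 727 regions this
  shifts the CD test statistic by about one standard deviation — enough to
  produce occasional marginal CD p-values even though CD is unenriched.
- The pipeline consumes aligned reads; alignment-stage artefacts
  (multimappers, blacklist regions) must be handled upstream.
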