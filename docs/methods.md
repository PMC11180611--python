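# Methods

This note records the models, conventions and numerical choices behind
`atacqc`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Coordinate and file conventions

All coordinates are 0-based, half-open (BED convention). Fragment files
follow the common five-column dialect (chrom, start, end, barcode,
count), optionally gzip-compressed, `#` comments allowed. Two dialects
exist in the wild — pre-collapsed rows with a count column and
one-row-per-read files — and both are accepted: rows identical in
(chrom, start, end, barcode) are collapsed at read time with counts
summed, which is the canonical form all metrics are defined on. Any
transposase-shift correction is assumed to have been applied by the
upstream fragment writer; the toolkit never re-shifts. Gzip output is
written with a zeroed mtime and empty embedded filename so identical
inputs and seeds produce byte-identical files.

Interval-overlap queries (FRIP, waterfall, annotation) run against
per-chromosome merged, sorted interval arrays via binary search; for
any-overlap membership this is exactly equivalent to querying the raw
set, and the tests cross-check it against exhaustive pairwise scans.

## Barcode correction

The rule is deliberately literal: exact whitelist match, or a unique
whitelist entry at Hamming distance 1. Two or more distance-1 entries
make the observation ambiguous, and ambiguous reads are left
uncorrected — no quality-weighted posterior tie-break. This is
conservative and deterministic; on sparse whitelists (thousands of
entries of length 16 in a 4^16 space) ambiguity is rare, and the
expected valid fraction is close to the binomial bound
P(0 or 1 substitutions) = (1−e)^L + L·e·(1−e)^(L−1). Lookup is O(1)
per read via a precomputed hash of the whitelist's full
single-substitution neighbourhood (|W|·3L keys).

## Bead-multiplet detection

Candidate pairs are built by inverting a coordinate→barcodes index over
barcodes with at least `min_unique` (default 1,000) unique fragments,
never by all-pairs intersection; pairs must share at least `min_shared`
(default 5) exact coordinates before being scored with the Jaccard
index of their fragment-coordinate sets. The Jaccard distribution is
thresholded with Otsu's method on log10 scores — the
background/multiplet bimodality spans orders of magnitude and lives in
log space — and above-threshold pairs are merged transitively through
connected components.

Otsu *always* produces a split, including inside a unimodal background
distribution when no multiplets exist. A split is therefore accepted
only when the two classes are at least `min_separation` (default 1.0)
decades apart in mean log10 Jaccard. Genuine bead multiplets share the
majority of a nucleus's fragments (J ≈ 0.1–1) while coincidental exact
collisions between unrelated barcodes sit at J ≈ 10⁻³–10⁻⁴, so the
guard rejects only within-mode splits. Without it, a sample with no
multiplets would see the upper tail of the background class merged
(~17% of eligible barcodes in simulation, against the ≤1% expectation
for multiplet-free chemistry).

## Per-barcode metrics

* duplication rate = 1 − unique/total. (The complementary ratio
  unique/total is sometimes quoted as "duplicate rate" in the
  literature; this package always uses the duplicate-fraction form, so
  "50% duplicates" means unique/total = 0.5.)
* TSS enrichment: both fragment ends are Tn5 insertion sites
  (positions `start` and `end − 1`). Insertions are binned by
  strand-oriented offset from each TSS over ±2,000 bp; a cut site
  inside several TSS windows counts in each. Contributions are
  read-count-weighted ("depth" rather than unique-fragment counts); the
  score is mean depth over the central ±50 bp divided by mean depth
  over the outermost 100 bp of each flank plus a pseudocount of 0.1.
  Window, centre, flank and pseudocount are parameters; the defaults
  follow the ENCODE-style recipe. Scores are depth-scale-invariant up
  to the pseudocount, which matters only for very shallow barcodes.
* FRIP: any-overlap of the fragment interval with the peak set, each
  fragment counted once regardless of how many peaks it touches.
* Fragment-length medians are over unique fragments, not read-weighted.
* Cross-file agreement: per-barcode Jaccard of coordinate sets between
  two fragment tables, summarised as the union-size-weighted mean —
  used to compare two processing routes over the same reads.

## Cell calling

Barcodes with fewer than 10 unique fragments are dropped. Otsu's
threshold — implemented exactly as the exhaustive between-class-variance
maximiser over histogram bin boundaries (default 100 bins), ties broken
toward the lowest edge within float tolerance — is applied twice: to
log10 unique-fragment counts (counts are log-bimodal, as in knee plots)
and to TSS enrichment on its linear scale (already a normalised ratio).
A cell must pass both thresholds; requiring the conjunction rejects
high-count barcodes with background-level TSS signal (debris,
ambient-dominated droplets). Note that with well-separated modes the
maximiser sits at the upper edge of the low mode rather than
mid-valley; any boundary in the empty gap partitions the data
identically.

## Downsampling, saturation and economics

Reads are thinned by independent Bernoulli retention per read unit
(binomial per collapsed row), the behaviour of read-level FASTQ
subsamplers; it is order-independent with respect to collapsing.
Target-depth mode derives one global retention fraction from the cell
set's current mean depth; upsampling is refused.

Sampling reads with replacement from a finite per-cell pool of N unique
molecules gives E[unique] = N(1 − (1 − 1/N)^r) after r reads, and the
50%-duplication depth of that exact process is r = 1.5936·N (the root
of (1 − e^(−x))/x = 1/2). The package does not assume that process:
it fits a Michaelis–Menten hyperbola with asymptote pinned at 1 to the
observed duplication-vs-depth points (so the fitted K_dup *is* the
50%-duplication depth) and, separately, a Langmuir isotherm to
unique-yield-vs-depth. The two fits are intentionally independent —
they are descriptive curves, not an internally consistent mechanistic
model — and nonlinear least squares is initialised from
double-reciprocal linearisations with 10⁻⁸ relative tolerance. When the
subsampling points span depths up to ~2.5 reads per unique molecule,
the fitted K_dup recovers the exact-sampling saturation depth to within
a few percent; extrapolating from far shallower data inherits the usual
risks of hyperbola extrapolation.

Cost arithmetic: sequencing cost = cells_sequenced × saturation depth ×
price per million reads (default $2.875/M), rounded half-away-from-zero
to whole dollars; total cost per cell = (assay price + sequencing
cost) / recovered cells, rounded to 3 decimals. `cells_sequenced`
defaults to the recovered-cell count; it exists because a platform
whose purchase unit recovers more cells than the standard 5,000-cell
experiment keeps its sequencing quote at the standard size. Expected
unique fragments in peaks = fitted unique yield at saturation × median
FRIP.

## Read-fate waterfall

The five categories are constructed to be disjoint and exhaustive:
duplicates are counted as count − 1 per unique fragment (the first read
of each fragment is the unique one), so the fractions sum to 1 exactly.
The waterfall is a per-sample quantity; aggregate over samples by
weighting with total raw reads.

## The simulator

`SimConfig` defaults describe a small, healthy droplet experiment: two
10-Mb chromosomes, 500 disjoint 500-bp peaks, 200 TSSs (30% at peak
centres), 200 cells of library complexity N = 5,000 unique molecules
sequenced to a mean of 10,000 reads (gamma-Poisson dispersed, ≈46%
duplicates), in-peak probability 0.6 (the FRIP regime of a good PBMC
run, and the regime implied by published per-cell unique/in-peaks
yields), 15% of molecules starting within a Gaussian jitter (σ = 50 bp)
of a TSS, fragment lengths from a 60/40 gamma mixture with means
80/200 bp clipped to [20, 1000] bp, 2,000 ambient barcodes averaging 30
reads drawn from the pooled cell molecules (so ambient composition
matches cells but counts are low), a 5% bead-doublet rate, and a 0.5%
per-base barcode substitution error rate.

Duplication arises mechanistically: reads are drawn with replacement
from the cell's molecule pool, so realised unique counts follow the
closed form above — which is what makes the saturation module testable
against an independent expectation. In-peak fragment starts are placed
on a 5-bp grid within each peak, a coarse stand-in for the preferred
insertion positions of Tn5 in real chromatin; it reproduces the low but
nonzero rate of exact fragment-coordinate collisions between unrelated
barcodes that gives the multiplet detector's score distribution its
background class. Everything is driven by one seeded generator;
identical configs give byte-identical outputs.

What the simulator does **not** emulate: genome sequence and
mappability, chromatin-state structure beyond uniform peaks,
nucleosome-phased length periodicity, sequencing-quality-dependent
error profiles, cross-cell doublets (two nuclei in one droplet, as
opposed to one nucleus with several beads), batch effects, or
platform-specific artefacts. Passing tests therefore demonstrate the
*algorithms* behave correctly under a controlled generative model whose
assumptions are stated, not that any particular real platform will show
these numbers.

## Problem sizes and tolerances

Tests and the acceptance script run on simulations of 40–500 cells and
0.25–6 million reads — large enough for the binomial/Monte-Carlo
tolerances used (2–10%, stated per test) while keeping the whole suite
around a minute. Degenerate inputs are explicit errors: constant input
to Otsu, fewer than two barcodes above the cell-calling floor, fewer
than three distinct depths for a saturation fit, upsampling requests,
raw-read totals below the fragment table's read count.

## Known limitations

* Ambiguous Hamming-1 matches are discarded rather than resolved by
  base quality; recovery is slightly lower than quality-aware
  correctors on real data.
* Multiplet detection needs constituent barcodes above the 1,000-unique
  floor; multiplets among shallow barcodes are invisible.
* The saturation fit is a two-parameter hyperbola; libraries with
  strongly heterogeneous per-cell complexity can deviate from it, and
  the reported standard errors assume independent points.
* TSS enrichment for barcodes with very few fragments is dominated by
  the pseudocount and is only meaningful comparatively.
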