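# Methods

## Coverage model

Sequencing fragments are assumed to be 190 bp; each uniquely mapped read
contributes one fragment midpoint (`start + 95` on the plus strand,
`end - 95` on the minus strand, clamped to the chromosome). All
coordinates are 0-based half-open; bin *i* of a track covers
`[100 i, 100 (i+1))`. Depth normalization scales counts to 5,000,000
mapped reads. The midpoint total is conserved through binning, and the
normalized track is invariant under duplicating every read.

The TSS metaprofile aggregates midpoints over TSS +/- 5 kb windows of all
transcripts, reversing minus-strand windows so positive offsets point
downstream of transcription. Overlapping windows from splice variants each
contribute (no deduplication — the aggregate is over transcripts, not
loci). Each offset-bin count is divided by the total count across all
windows of the sample, so the profile integrates to 1; per-bp resolution
is available via `bin_size=1`, but the default is the 100-bp bin the
tracks use. An alternative reading of the normalization — dividing by the
sample's total mapped reads instead of the in-window total — only rescales
the curve, so the default follows the per-window-total (density) form.

Smoothing is LOWESS (statsmodels; locally weighted linear regression),
default span 0.05. The smoother reproduces constants and straight lines
exactly, which the tests rely on. Peak calling on the smoothed curve
(`profile_peaks`) requires a prominence of at least 10% of the curve's
dynamic range and a 500-bp minimum separation between maxima. The
separation guard exists because two near-equal summits straddling a
shallow one-bin dip on a single enrichment feature both receive large
scipy prominences (each is measured down to the far valley); 500 bp is
below the width of any feature of interest here (the planted bumps have
~700 bp FWHM) and a quarter of the +/- 1 kb bump separation, so real twin
flanking peaks are never merged.

## Enrichment caller

Windows of `window` bp (default 100) at a `step`-bp pace (default 100)
are tested against a Poisson null. The background rate is the genome-wide
mean midpoint count per window — `(total midpoints / genome bp) x window`
— or per-chromosome in `per_chromosome` mode. Significance is the
upper-tail probability P(X >= k) computed via the survival function of
`scipy.stats.poisson`; the threshold (default 1e-5) is strict
(`p < threshold`), so a window whose p equals the threshold exactly is not
called. Overlapping or abutting significant windows merge into regions;
with `window == step` this degenerates to merging runs of consecutive
significant windows.

Control filtering re-tests each region on the mock-IP (anti-GFP) sample:
the control midpoint count over the region span against the control's own
background rate scaled to the span (pooling span/window windows). Regions
with control p below the threshold are dropped. Using the control's own
rate (rather than the IP rate) makes the filter a statement about the
control sample; calling a sample against itself therefore removes every
region, which the null-calibration test exploits.

No multiple-testing correction is applied anywhere: the fixed strict
1e-5 threshold is the operating point, and reported p-values are raw.

Power note: at the default background of 0.2 midpoints per 100-bp bin, a
100-bp window inside a fold-8 enrichment holds Poisson(1.8) midpoints
while significance needs k >= 5 (P(X >= 5 | 0.2) ~ 2e-6), so per-window
detection power is ~4%. Detecting kilobase-scale domains therefore
requires windows matched to the domain width; the recovery experiment
uses `window=1000, step=100`, which recovers >= 1 kb fold-8 domains with
~97% sensitivity at a ~0.3% false-call rate.

## Occupancy and signatures

Occupancy of `[start, end)` is
`midpoints x 5e6 / (total_reads x length_kb)` — reads per kb per 5 million
mapped reads. (An alternative constant of 1,000 instead of 1 kb circulates
for this quantity; the per-kb form is used because it makes the background
scale coherent, and the scale is a parameter of `interval_occupancy`.)
Intervals are transcript-anchored: TSS window `[TSS-2500, TSS+2500)`,
promoter = the 2.5 kb strand-aware upstream of the TSS, gene body =
`[txStart, txEnd)`; all are clamped to the chromosome and use the clamped
length. Counting uses fragment midpoints, consistent with the tracks.
Classification is per transcript; a gene-level view should take the
transcript with the maximal row norm.

The background `b` is the arithmetic mean of mock-IP occupancy over all
gene TSS windows and all stages. The no-mark cutoff is `sqrt(d) x b` for a
`d`-dimensional row (d = 8 for 2 marks x 4 stages): the norm of a row
sitting exactly at background in every dimension. A row with norm strictly
below the cutoff is NO_MARK; b = 9.12 gives 25.80. Note the screen's
operating characteristics depend on ChIP enrichment: in an IP library a
substantial fraction of reads sits in enriched regions, so unmarked loci
fall measurably *below* the mock-IP background b and clear the cutoff with
margin. In a hypothetical signal-free IP library, background noise alone
would put ~half of unmarked genes above the cutoff.

Deterministic signature rules, in units of b with thresholds
`c_rep = 1.5` (absent), `c_act = 3` (clearly present), `f_min = 3`
(de novo gain), applied with precedence
NO_MARK > ROD_SPECIFIC > NONROD_RETINAL > UBIQUITOUS > OTHER:

* ROD_SPECIFIC — H3K27me3 < c_rep b at all stages; H3K4me2 < c_rep b at
  E17.5 and PN1; H3K4me2 at PN15 >= c_act b and >= f_min x max(E17.5, b).
  Optionally the gain conditions must also hold on gene-body H3K4me2.
* NONROD_RETINAL — H3K27me3 >= c_act b at all stages and H3K4me2 < c_act b
  at all stages ("high repression, lower activation"). A lower bound on
  H3K4me2 is deliberately not imposed: at realistic background counts a
  `>= b` condition on four stages is a coin flip for genuinely
  background-level values and would halve recall without sharpening the
  biology.
* UBIQUITOUS — H3K4me2 >= c_act b at all stages, H3K27me3 < c_rep b.

These thresholds are a testable, deterministic stand-in for the
unsupervised route; `hierarchical_cluster` provides the latter
(average linkage; Euclidean or uncentered correlation, the similarity
used by the classic clustering software — zero-variance rows get distance
1 to everything).

Classification is invariant under uniform depth rescaling since the
occupancy formula removes depth.

## Group statistics

`pooled_t_test` is the classic two-sample equal-variance t-test, coded in
closed form (the p-value comes from the t distribution with n+m-2 df);
star annotations: `*` 0.05 > P > 0.01, `**` 0.01 > P > 0.001,
`***` P < 0.001. Promoter-vs-body comparisons run it per (mark, stage)
column over a gene set.

Genotype comparisons (wt vs rd1) report the mean occupancy fold and the
pooled t-test for one (mark, stage) column over a gene set. By default the
mutant occupancies are first rescaled by a between-library composition
factor: depth normalization fixes the read total, so when one library
loses a large signal compartment (rd1 losing rod-gene H3K4me2), the
occupancies of *unchanged* genes inflate by the lost fraction. The factor
is the exponentiated mean of the shortest half of the per-gene log-ratio
distribution (half-sample mode) over all shared genes — robust even when
the truly changed genes all sit on one side of the distribution, where a
median or symmetric trimmed mean stays biased. `normalize=False` gives the
raw comparison. In data where the changed compartment is a tiny fraction
of the genome the factor is ~1 and the correction is a no-op.

## Synthetic study generator

The generator emulates the full design: 2 chromosomes x 8 Mb, 250 genes
(50 per class: ROD, NONROD_RETINAL, UBIQUITOUS, SILENT, DOWN) placed
non-overlapping with alternating strands, lengths uniform in 2–20 kb and
at least 15 kb of intergenic space (so +/- 5 kb profile windows never
touch a neighbour's signal); 2 marks x 4 stages x 2 genotypes IP libraries
plus 4 mock-IP controls. Per-bin counts are
`Poisson(lambda_bg x (1 + fold x shape))` with `lambda_bg = 0.2` per
100-bp bin. The H3K4me2 TSS shape is two Gaussian bumps (sigma 300 bp) at
+/- 1 kb; H3K27me3 and gene-body contributions are flat. Shapes are
normalized to mean 1 over their window so "fold f" means the TSS window
holds (1+f) x background counts in expectation. Planted folds by stage
(E17.5, PN1, PN7, PN15):

| class          | H3K4me2 TSS | H3K4me2 body | H3K27me3 TSS (+body for NONROD) |
|----------------|-------------|--------------|---------------------------------|
| ROD            | 0,0,4,8     | 0,0,4,8      | 0,0,0,0                         |
| NONROD_RETINAL | 1,1,1,1     | —            | 6,6,6,6                         |
| UBIQUITOUS     | 8,8,8,8     | —            | 0,0,0,0                         |
| SILENT         | 0           | —            | 0                               |
| DOWN           | 8,6,2,0     | —            | 0,1,2,4                         |

The rd1 genotype multiplies the whole H3K4me2 intensity (baseline plus
planted signal) over ROD-class gene footprints by `rd1_rod_scale = 0.4`,
modelling the loss of the rod compartment; nothing else changes. Reads are
36 bp and placed so that the 190-bp midpoint rule recovers the generating
bin exactly (strands drawn uniformly, flipped only where a chromosome edge
would make the read invalid), making the generator-to-pipeline round trip
bit-exact at bin resolution. A fixed seed yields byte-identical fixture
files; every sample draws from an independent child of one seed sequence.

Genome-size rationale: with 250 genes on 16 Mb the IP libraries carry
~20–45% of reads in planted signal — a realistic ChIP enrichment share —
which gives the no-mark screen the background suppression it relies on
(see above) while keeping every experiment seconds-scale. The DOWN class
deliberately matches none of the deterministic rules and must land in
OTHER.

What the generator does not emulate: mappability and GC structure,
fragment-length variation, duplicate reads, replicate structure,
between-stage depth drifts beyond signal composition, or degeneration
kinetics in rd1 (a single scale factor stands in for progressive rod
loss). Passing tests therefore demonstrate correctness of the pipeline's
arithmetic and decision rules under the stated generative model, not
robustness to those real-data artifacts.

## Numerical choices and degenerate inputs

* Strictness: significance uses `p < threshold`; the no-mark rule uses
  `norm < cutoff` (a row exactly on the cutoff stays "marked").
* `poisson_upper_tail(0, lam) = 1` exactly; the scipy survival function
  agrees with direct term-by-term summation to 1e-12 over the tested
  grid (lambda <= 10, k <= 50) and is stable to lambda ~ 1e4.
* Empty inputs raise: empty track (rate estimation), no midpoints in any
  TSS window (undefined profile normalization), empty control set,
  zero-length intervals, zero pooled variance, gene sets smaller than 2.
* A zero mutant mean in a genotype comparison reports an infinite fold
  and sets a flag rather than raising.
* Ties in clustering follow scipy's deterministic linkage order; output
  region lists are sorted by (chromosome, start), so results do not
  depend on chromosome iteration order.
* Reads on chromosomes absent from the genome table are dropped with a
  logged count (annotation/genome mismatches should not abort a run);
  malformed rows, by contrast, raise with their line number.

## Problem sizes

Defaults used by the test suite and `scripts/acceptance.py`: the 2 x 8 Mb
cohort above; null calibration and peak recovery on 2 x 2 Mb background
genomes (40,000 windows), 20 peaks per replicate x 20 replicates; 100
random intervals for the occupancy recount. The full suite runs in well
under a minute on one core.
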