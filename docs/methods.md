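# Methods

This note documents the models, parameter choices and numerical
conventions behind `circdif`, and what the synthetic-data tests do and
do not demonstrate about real data.

## Coordinates and formats

All genomic intervals are 0-based half-open (BED convention)
internally; GTF input (1-based inclusive) is converted on read. Readers
reject malformed input (reversed coordinates, ragged matrix rows,
non-finite values, duplicate ids) with the offending line number rather
than coercing. Overlap logic is strand-blind throughout; strand is
carried for bookkeeping only. The mitochondrial chromosome is
recognized by the configurable name set {chrM, MT, chrMT}.

## Junction calling and merging

A split-read alignment is a read whose prefix (segment 1) and suffix
(segment 2) map separately to the same chromosome. A circular template
is evidenced when segment 1 maps genomically *downstream* of segment 2;
collinear segment order is an ordinary linear split and is ignored.
Both segments must contribute at least `min_non_overlap` (default
10 bp) of genomic span outside their mutual overlap, which suppresses
near-tandem duplication artifacts. The called circle spans
(chrom, min start, max end); identical junctions within a sample are
aggregated, each read contributing one split read. Inter-chromosomal
segment pairs are skipped and counted — complex multi-locus circles are
a small minority in non-tumor tissue and are out of scope.

Merging links two circles when *both* |Δstart| and |Δend| are strictly
below `d_min` (default 10 bp) on the same chromosome. The pairwise
(per-breakpoint) interpretation was chosen over a single-endpoint rule
because the latter would chain circles that share only one breakpoint.
Clusters are connected components under single linkage; at 10 bp the
chaining risk is negligible. The merged representative keeps the
coordinates of the highest-support member (ties: smallest start, then
smallest end) — a real observed junction — rather than a min/max
envelope, and its split reads are the cluster sum, so total split-read
mass is conserved and the operation is idempotent and
permutation-invariant.

Filtering retains circles with ≥ `min_split_reads` (default 2) support,
length ≤ `max_length` (default 100 kbp) and a non-excluded chromosome,
logging removal counts per criterion.

## PpGC quantification

Per gene *i* and sample, the raw PpGC is the sum of split reads over
every circle overlapping the gene by ≥ 1 bp (half-open semantics, the
bedtools default; no minimum-fraction option). A circle spanning
several genes contributes its full split-read count to each — the
summation is deliberately not apportioned. The raw sum is scaled by
L_Max/L_i and equalized as log2(scaled + 1).

"Longest gene found in the dataset" is interpreted as the longest gene
with at least one circle assignment anywhere in the run (config switch
`l_max_source = detected|annotation`): this makes L_Max data-dependent,
which matches the phrase "found in the dataset", at the cost of making
PpGC values comparable only within a run. Genes with no assignment are
retained at final PpGC 0 (log2(0+1)), so the matrix shape is stable
across cohorts sharing an annotation.

Full-gene detection flags genes entirely contained in at least one
circle; per-sample fractions use the total annotated loci as
denominator, and group summaries report mean ± SEM of those fractions.

## DifCir

Group means of final PpGC are compared per gene. "Student's t-test" is
implemented as the classic pooled-variance two-sample t (an
unequal-variance Welch switch exists). The up-DPpGC gate is
delta > theta (strict, "more than" a onefold log2 change) together with
p <= alpha (inclusive, matching a −log10 p ≥ 2 cut at alpha = 0.01);
down-DPpGCs are symmetric. Raw p-values are thresholded — no multiple
testing correction enters the call — but a Benjamini–Hochberg column is
always emitted for transparency.

Degenerate variance: both groups constant and equal gives p = 1 (no
evidence); both constant but unequal gives the minimum representable
positive double with a warning, so that the mean difference decides the
call without inventing a variance prior.

Chromosome enrichment is an upper-tail hypergeometric test per
chromosome (population = all tested genes, successes = up-DPpGC genes,
draws = genes on the chromosome), BH-adjusted across chromosomes. The
gene-length regression is OLS of −log10 p on L_i over up-DPpGCs with
R² = 1 − SSR/SST; a constant response defines R² = 0.

Calibration on simulated nulls (2000 genes × 19 samples, 50
replicates) keeps the p ≤ 0.01 fraction within binomial 99% bounds —
expected, since the pooled t is exact under the normal null.

## Democratic voting

The vote threshold is the ceiling of the mode of the group's positive
final PpGC values. Zeros are excluded — the point mass at zero (genes
without circles) would otherwise always be the mode. The mode is the
argmax of a Gaussian KDE with Silverman bandwidth on a fixed 1024-point
grid over [0, max]; fixed grid and bandwidth keep the estimate
deterministic. Because the grid discretizes the argmax by up to half a
step, a mode within one grid step of an integer is snapped to that
integer, preserving the convention that an exactly-integer mode votes
at its own value. Thresholds are computed independently per group; a
sample votes at value ≥ threshold, and ≥ 3 votes (default) make a
CPpGC. The distribution is taken over all positive gene-sample values
of the group (not per-gene means). Fewer than 10 positive values abort
with advice to set a manual threshold.

## Size profiling and the exact Wilcoxon test

Histograms use 1 bp bins up to 10 kbp (configurable). Smoothing is a
centered moving average (default 31 bp, odd window enforced) with
reflect padding, conserving mass up to boundary effects. Local maxima
must be strictly greater than neighbors with prominence ≥ 5% of the
global smoothed maximum (suppresses noise peaks); the periodicity
estimate is the median spacing of consecutive maxima, absent when fewer
than two peaks exist. No spectral estimation is attempted.

The unique-count comparison uses an exact two-sided Wilcoxon rank-sum
test: the full null distribution of the rank sum is built by dynamic
programming over doubled mid-ranks (exact under ties), and the
two-sided p doubles the smaller tail, capped at 1. Exact enumeration is
used up to a combined n of 25; beyond that the normal approximation
with tie correction takes over. Under complete separation of 10 vs 9
samples the exact p is 2/C(19,9) ≈ 2.165 × 10⁻⁵ — the attainable
minimum for that design.

## ECTR

The estimator works on circle consensus sequences directly: a sequence
qualifies at threshold k when it carries ≥ k non-overlapping TTAGGG
motifs in one orientation (each sequence is scored as the max of the
TTAGGG and CCCTAA counts, never their sum, so a repeat tract and its
complement are not double-counted); the per-sample ECTR is 6 bp × total
motif occurrences in qualifying sequences, in kbp. This makes the
estimate deterministic, monotone non-increasing in k, and invariant
under reverse-complementing the input. Read-level estimation with
coverage normalization is a non-goal: after rolling-circle
amplification, per-read depth is not proportional to molecule count,
and no depth normalization is attempted. k defaults to 4.

## DEP calling

Per fraction, each protein is tested with a one-sample t on its
per-pair log2 ratios (case/control); the "average log2 ratio" is the
mean of per-pair log2 ratios, consistent with the paired test (not the
log of the ratio of means). Proteins missing (or non-positive) in more
than half the pairs are excluded with a logged count. Storey q-values
use pi0 estimated as pi0(lambda) = #{p > lambda}/(m(1 − lambda)) on the
grid lambda = 0.05..0.95 (step 0.05) with a cubic polynomial smoother
evaluated at the largest lambda — the behavior of the reference q-value
implementation — clamped to (0, 1]; for m < 100 the single-lambda
(0.5) estimate is used for stability. With pi0 = 1 the q-values equal
BH-adjusted p-values exactly, an identity the tests assert. The DEP
gate is q < 0.05 and |average log2 ratio| > 0.38; fractions are
analyzed independently and a protein's overall DEP status is its call
in any fraction.

## Integration

Gene/protein identifiers are matched by case-folded symbol (identity
mapping by default; an explicit two-column mapping may be supplied, and
collisions of two genes onto one protein are rejected). A tandem is an
up-DPpGC whose protein is a DEP in ≥ 1 fraction; concordance means the
eccDNA delta and protein ratio share a sign. Risk lists are plain
one-symbol-per-line files; the bundled fixtures ship only gene lists
printed in full (17 Harmonizome tandem symbols, 4 GWAS-catalog tandem
symbols, 19 GWAS-catalog up-DPpGC symbols, and a 10-gene printed subset
of the 27 murine RDC neural genes — the full RDC catalog must be
supplied by the user). Overlap percentages are reported to one decimal.
The RDC comparison pools all (gene, sample) PpGC values per group and
reports means, their ratio, and an exact Wilcoxon p (t-test
configurable).

## Synthetic cohorts

The generator's defaults encode the emulated study design: 10 control
vs 9 case samples; ~480 background circles per control sample (Poisson)
with a 6.0× case multiplier; circle lengths from equal-weight normal
components at k × 200 bp (k = 1..5, sd 20 bp, truncated positive) plus
a 1% log-uniform tail up to 99 kbp; 5% mitochondrial circles; six
hotspot genes receiving 5 extra circles per case sample at ≥ 4 split
reads; 25 telomeric circles of 200 TTAGGG repeats per sample (30 kbp
planted ECTR, half emitted on the complementary strand); and one
protein fraction of 800 proteins (panel ids reuse gene ids, hotspots
first, so eccDNA–DEP tandems exist by construction) with 40 planted
±1.0 log2 shifts over 5 matched replicate pairs and 0.2 log2 replicate
noise — a typical DIA replicate variability. Chromosomes are scaled to
19 autosomes of 8 Mb plus chrM, which preserves all structural
properties (scatter, density, overlap statistics) at desk scale; test
and acceptance runs use 100–480 circles per control sample.

Split-read simulation emits a configurable number of reads per circle
whose segments flank the junction in inverted order with ±2 bp
coordinate jitter — chosen so that merging at D_min = 10 bp coalesces
the reads of one circle while distinct circles stay separate. Exact
one-circle-per-planted-circle recovery holds only while planted circles
are not themselves near-duplicates, so the recovery test runs at
reduced circle counts where duplicate collisions are vanishingly rare.

What the generator does *not* emulate: sequence errors and mappability,
RCA amplification bias, chimeric multi-fragment circles, biological
covariance between eccDNA output and protein abundance (tandems arise
by construction, not by a shared latent cause), and realistic gene
annotation complexity (single-interval genes only). Passing tests
therefore demonstrate correctness of the statistical machinery and
pipeline plumbing under the assumed data model, not robustness to
alignment artifacts in real sequencing data.

## Determinism

All randomness flows through `numpy.random.default_rng` seeded from the
configuration; a fixed seed yields byte-identical datasets and run
directories (the manifest stores run-relative paths so two runs of the
same seed hash equal). KDE grids, tie-breaks and sort orders are fixed
and documented above.
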