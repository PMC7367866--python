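# Methods

## The ladder model

A copy-number (cn) ladder is a single synthetic DNA molecule carrying four
artificial 600-nt elements repeated 1, 2, 4 and 8 times. Because the
repeats live on one molecule, their stoichiometry is exact by construction
— no mixing step can distort it. In a sequencing library the count of any
k-mer lying inside an element is therefore proportional to that element's
cn, and the four units form a graduated internal scale spanning an
eightfold dynamic range. Deviations from the expected 1:2:4:8 structure
measure the technical noise of the library itself (preparation bias,
sampling depth, sequencing error, duplication), which is what the package
exploits for calibration, replicate-free uncertainty estimation and
normalization.

Quantification is alignment-free: canonical 31-mer counting (the canonical
form of a k-mer is the lexicographic minimum of itself and its reverse
complement). A 600-nt element contributes 600 − 31 + 1 = 570 catalogued
k-mers; k-mers spanning element boundaries, spacers or flanks are excluded
from the catalog, so every catalogued k-mer has a single expected
multiplicity equal to its element's cn.

## Design (`cnladder.design`)

Elements are obtained by shuffling disjoint windows of a template sequence
(any genome FASTA, or a seeded random 1-Mb template by default — only the
base composition and the absence of homology matter). Shuffling preserves
the window's base multiset exactly, hence its GC content, while destroying
sequence identity. Every candidate is screened so that its longest exact
shared substring with the template (both strands) is at most 25 nt; a
candidate failing the screen is re-shuffled with a fresh seed (at most 100
attempts). The screen is a local exact-substring search — hashed
fixed-length words with binary search over the word length, plus explicit
extension for runs that could exceed the 32-bp word cap — which is stricter
than a heuristic database search for the same bound: an exact match is the
limiting case of any alignment hit.

Geometry defaults: element 600 nt, cn vector (1, 2, 4, 8), spacers 20 nt
(unique, random, screened), flanks 500 nt (one common pair shared by the
whole set, as a guard against coverage edge effects), 14 ladders per set.
Total molecule length 2×500 + 15×600 + 14×20 = 10,280 nt. Within a
molecule, copies of one element are placed as a tandem block and block
order is randomized per ladder; the arrangement is invisible to k-mer
quantification (junction k-mers are not catalogued), so this is a
convention, exposed in the configuration. Element canonical k-mer sets are
kept pairwise disjoint and disjoint from spacer/flank/junction k-mers, so
the catalog is unambiguous; assembly re-draws spacers and flanks until no
off-catalog k-mer collides with an element k-mer.

## Simulation (`cnladder.simulate`)

The read simulator is wgsim-like: fragments drawn uniformly along weighted
templates (template probability ∝ molar weight × length), Gaussian insert
(default 350 ± 50 nt, truncated to [2×read length, template length]),
125-nt paired reads from the fragment ends, uniform per-base substitution
errors (default rate 0.005). Indels and quality-dependent errors are
deliberately excluded: downstream k-mer analysis treats any error as k-mer
loss, which substitutions capture with the closed form (1−e)^k for the
surviving fraction — used directly as a test oracle. Qualities are a
constant Q30 placeholder; nothing downstream reads them.

Because a fragment cannot overhang a template end, the k-mer mass of a
template concentrates on an interior of about (length − insert) positions.
Coverage targeting and multi-template weighting use this effective length,
so interior coverage is uniform and commensurable across templates of very
different sizes (600-nt loci vs 10-kb ladder molecules).

Library manipulations follow the procedures used for the technical-variable
sweeps: exact-count subsampling without replacement (depth grid 1.00 → 0.10
in steps of 0.05), and duplicate injection — for duplication rate x, a
(1−x) fraction of the unique pool is kept and the remaining x of the target
size is resampled with replacement from the kept set (grid 0.10 → 0.95 in
steps of 0.05). The error sweep covers substitution rates 0.0 → 0.1 in
steps of 0.005.

### Synthetic diploid and related-pair samples

The diploid generator builds a genome blueprint of 600-nt segments with
400-nt pads: homozygous variant loci and a 2-copy background at two copies,
heterozygous loci at one copy. `depth` is the coverage of the 2-copy level.
Ladder molecules are spiked at half molarity so the 1-cn unit is
commensurate with heterozygous k-mers — the configuration in which ladder
and genome counts are directly comparable. The related-pair ("trio-like")
generator reuses one blueprint for two samples, flipping designated loci
heterozygous→homozygous (fold change 2) and homozygous→heterozygous (0.5).

Real libraries are overdispersed relative to Poisson. The generator models
this as lognormal per-segment (and per-ladder-molecule) coverage bias with
two components: a sequence-intrinsic part shared by all libraries from the
blueprint (`coverage_cv`, default 0.30 — chosen to match the
count overdispersion reported for germline-variant k-mers, where observed
standard deviations exceed the Poisson expectation by roughly this factor)
and an independent per-library residual (`library_cv`, default 0.10).
The split matters scientifically: shared bias cancels in between-sample
comparisons, while the independent residual does not. The ladder-informed
difference test dominates fold-change ranking when between-library
multiplicative noise is modest (the regime its own source data exhibit); if
the independent component were made dominant, log-ratio ranking would win —
a known limitation documented here rather than hidden.

Features the generators do not emulate: GC-dependent error profiles, PCR
chimeras, indels, mappability structure, real genome repeat content.
Passing tests therefore demonstrate the statistical machinery under
controlled overdispersed-Poisson conditions, not performance on real data.

### Mock communities

Nine species (one 100-kb random genome window each, a desk-scale stand-in
for windowed bacterial genomes), with relative abundances chosen so that
the A→B fold changes span {0.3, 0.6, 1, 2} and are unbalanced (sum of log
fold changes −1.86, window-median fold change 0.6), while A→C is exactly
balanced. Abundances satisfy the physical constraint Σaᵢ(FCᵢ−1)=0 for both
pairs, so designed fold changes are realized as relative-abundance ratios
without renormalization distortion. The ladder is spiked at 1% fractional
abundance; at that fraction a single spiked molecule lands at per-copy
coverage commensurate with the genome windows, so one ladder molecule is
spiked at desk scale (a full mixture works identically and costs more
simulation). For the normalization experiments, community A is subsampled
to 60% of its library size to create the depth imbalance that makes
normalization necessary.

## Quantification (`cnladder.kmerquant`)

Counting packs each k-mer into a 64-bit integer, two bits per base, so
integer order equals lexicographic order; reads are joined with an invalid
separator byte and all windows of a batch are extracted and canonicalised
in a handful of vectorised passes. Windows containing non-ACGT characters
are dropped (counted), reads shorter than k are skipped (counted), and the
count-conservation identity Σcounts = Σ(len−k+1) − skipped is tested.

Read partitioning assigns a pair to a ladder when ≥ 5 of its k-mers (both
mates) are catalogued to that ladder; pairs reaching the threshold for more
than one ladder are ambiguous and excluded. Five hits is far below the
≥ 65 catalogued k-mers of an error-free element-overlapping read but above
any realistic chance hit. Pairs lying wholly within the common flanks carry
no ladder-specific k-mers and remain unassigned (a few percent, set by the
flank-to-molecule length ratio). Per-ladder bins can then be subsampled to
the smallest bin ("depth equalization"), which removes mixture molarity
errors from all downstream per-ladder statistics.

Ladder metrics: ordinary least squares of catalogued k-mer count on cn over
all k-mers (per-unit-median regression is available as a mode; the
all-k-mer default matches how the scatter relationship is usually drawn),
absent catalogued k-mers counted as 0 since dropout is the signal at high
error or low depth; per-ladder median counts per unit; successive-cn ratios
(2/1, 4/2, 8/4) per ladder with mean and SD over all ladders × 3 pairs; CV
per unit; and the overlap coefficient of adjacent per-unit count histograms
(unit-width integer bins, Σ min of the two empirical masses).

## Calibration and testing (`cnladder.calibrate`)

Calibration anchors the 2-cn unit median to the median count of the
accompanying sample (for a diploid genome the bulk of k-mers are 2-copy, so
this expresses sample counts in cn units). The dynamic-range fraction is
the share of sample k-mer counts between the calibrated 1-cn and 8-cn
medians — the bounds are the unit medians themselves, the natural reading
of the eightfold range.

Technical variation: per cn unit, the distribution of count differences
(B − A) over catalogued ladder k-mers between two samples at comparable
depth. The means should centre on 0 (a warning fires when |mean| exceeds
half the SD — a depth or normalization offset); the SDs are the
replicate-free estimate of technical noise at each count level.

The fold-difference test assigns each feature the cn level nearest (log
scale) to the smaller of its two counts, forms z = (B−A)/SD(level), and
refers it to a standard normal — the SD comes from hundreds of ladder
k-mers, so the t distribution's degrees of freedom are effectively
infinite. Differences are taken on raw counts (log-scale testing is not
exposed; raw differences are what the ladder SD measures). One-sided
upper-tail is the default; `two-sided` tests |difference| exceedance, which
is the form used to detect changes in either direction. Benjamini–Hochberg
adjustment at α = 0.05; SD = 0 at a level yields the limiting p (0 or 1)
and a flag. Tests are per k-mer; callers may aggregate k-mers per locus by
mean if desired.

ROC/AUC uses the Mann–Whitney identity with midranks for ties. In the
ranking comparison, "significance" means |z| (equivalently 1 − p of the
two-sided test) and "raw fold change" means the plain ratio B/A — the
comparison as usually made; the ratio inherently ranks decreases at the
bottom, which is a large part of why significance ranking wins. The power
check applies the same comparison at the q ≤ 0.05 operating point:
sensitivity against a raw fold-change threshold matched for specificity.
When both rankings are symmetrised (|z| vs |log fold change|) they are
close, with the significance ranking ahead in the high-specificity region
under the default noise model — that symmetric comparison is a near-tie,
not the claim tested.

## Normalization (`cnladder.normalize`)

Three scaling-factor methods implemented from scratch on raw counts:

- **MR** (median of ratios, DESeq2 definition): reference = per-feature
  geometric mean over samples on features with no zeros; factor = median of
  count/reference. Cross-checked against DESeq2's
  `estimateSizeFactorsForMatrix` to 7 digits.
- **TMM**: M = log2 ratio vs a reference sample (default: upper quartile
  closest to the mean), A = average log2 abundance, over features positive
  in both; 30%/5% double trimming by quantiles; factor = 2^(precision-
  weighted mean M), weights 1/(1/x + 1/x_ref); unweighted mean available.
  Implemented on raw counts without library-size pre-division, so TMM
  factors are depth-inclusive and directly comparable to MR and UQ factors.
- **UQ**: 75th percentile of nonzero counts (linear interpolation between
  order statistics).

TMM and UQ factors are rescaled to geometric mean 1 across samples (MR's
own convention already yields unit factors for identical samples).
Normalized counts are count/factor, so factor *ratios* are the meaningful
quantity; scaling one sample by c multiplies its factor ratio by c exactly
for MR and UQ.

Anchoring modes: `sample` derives factors from the non-ladder features
(what standard pipelines do); `ladder` derives them from the ladder
features only and applies them to everything. Because the ladder's
composition is invariant across samples, ladder-anchored factors estimate
pure depth/technical scale and preserve genuine compositional differences —
the defining property tested (factors invariant to arbitrary changes in
non-ladder rows). RLE diagnostics (per-feature log2 ratio to the
across-sample median, zero-median features excluded with a counter)
summarize residual structure per sample.

`evaluate_normalization` re-estimates technical variation from the
*normalized* ladder rows (so each anchoring mode is judged with its own
null), runs the two-sided ladder-SD test per feature, reports the AUC of
|z| against the changed/unchanged truth and the median observed fold change
per designed group.

## Numerical choices and degenerate inputs

- k-mers are uint64-packed (k ≤ 31 used throughout; the codec supports 32);
  equality and ordering match string semantics, property-tested.
- OLS with all counts equal reports R² as NaN rather than failing.
- Ratio statistics skip units with zero median denominator.
- Quantiles everywhere use numpy's linear interpolation convention.
- The homology screen's binary search is exact for shared lengths ≤ 32 and
  switches to seed-and-extend beyond; validated against an O(nm) dynamic-
  programming oracle in the tests.
- Seeds: every public entry point takes a seed or Generator;
  `SeedSequence.spawn` derives independent child streams, keeping all seeds
  below 2³¹.

## Problem sizes

Defaults in the test and acceptance runs: 14 ladders designed against a
1-Mb template; equimolar libraries at 100× per-copy depth (~75k read
pairs); technical sweeps on a 3-ladder set at 40–60×; diploid/trio samples
with 300–380 loci at 30× diploid coverage; communities of 9 × 100-kb
genomes at 150k pairs per library with two spiked ladder molecules — sized
so per-unit ladder counts stay well above the regime where quantile-based
factors ride on extreme order statistics (the 75th percentile of the
ladder's count distribution sits at the 4-cn→8-cn cluster boundary, so UQ
factors need per-unit counts ≳ 20 to be stable). These sizes keep every
statistic's sampling error well inside the asserted tolerances while the
whole suite stays desk-scale.

## Provenance headers

Tabular artifacts (TSV/BED/JSON) begin with comment lines carrying the tool
version, subcommand, seed and a config hash. FASTA/FASTQ have no portable
comment syntax, so sequence artifacts carry provenance in the run log and
companion tables instead.
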