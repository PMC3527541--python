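# Methods

## Coordinate conventions and interval arithmetic

Printed locus strings (`chr16:22684122-22685282`) are 1-based inclusive,
the genome-browser dialect; the parser also accepts the unicode ratio
separator, en/em/minus dashes and thousands commas, so table
transcriptions can be consumed verbatim. Internally every interval is
0-based half-open, and BED input/output is passed through natively in that
convention. Parsing is lossless: re-serialising an interval reproduces the
printed 1-based string modulo separator normalisation.

Overlap is defined as sharing at least one base; no minimum reciprocal
overlap is imposed. Strand is ignored. Genome builds are opaque labels on
a declared assembly (a UCSC-style chrom.sizes table); no liftover is
performed, so sets being compared must share a build. Merging produces the
minimal disjoint interval list with the same base union; book-ended
intervals are joined (the bedtools convention). *Feature coverage* counts
each target once no matter how many cover intervals hit it, while
recording every (target, cover) pair for reporting; *base coverage*
merges the cover set first so shared bases are not double-counted.

## The depletion model

With targets = *N* enhancer loci and cover = a CNV set covering merged
fraction *c* of the genome, the no-association null predicts
`E[covered targets] = N·c` and `E[covered target base fraction] = c`.
Reported statistics:

- observed covered-target count and base fraction (both are reported
  because published bar charts mix the two: bars show base fractions
  while counts are feature counts);
- fold = observed base fraction / *c* (0 when both are 0);
- 1-df chi-square goodness of fit on the {covered, uncovered} counts and
  an exact binomial test on the count, one-sided toward depletion by
  default (two-sided and enrichment alternatives by flag). Neither
  p-value is floored or clamped; values below double precision appear as
  computed. Note the common printed floor 2.2e-16 is an artifact of other
  software, not of these tests.
- optionally a permutation null: every cover interval is re-placed
  uniformly at random on its original chromosome with its length
  preserved (start ~ U[0, chrom_len − length]), and both statistics are
  recomputed per permutation. The empirical p uses the add-one correction
  `(1 + #{null ≤ obs}) / (1 + B)` so it is never zero. No gap/centromere
  exclusion mask is applied by default (real assemblies are not modelled
  here); the null preserves per-chromosome CNV density and lengths.

`N·c` is the convention used for published expected counts; it is exact
for point-like targets. For targets of non-negligible length the true
placement-null hit probability is slightly larger (an interval of length
M overlaps a target of length L with probability ≈ (L+M−1)/(C−M+1)); the
test suite checks the permutation null against this closed form, and the
expected-count comparison is made in the regime where the distinction is
immaterial (enhancers of ~1 kb versus CNVs of tens of kb on chromosomes
of tens of Mb).

The degenerate expectations c = 0 and c = 1 are rejected for the
parametric tests (both categories need positive null mass). At the null
mean the exact one-sided binomial p is the CDF at `N·c`, about 0.5 — not
1 — which is the expected behaviour of a one-sided exact test.

## Probe-design planner

"Resolution" follows a 3-probe detection rule throughout: the smallest
event reliably callable spans 3 probes, so resolution = 3 × spacing. This
reconciles a 100 kb backbone spacing with a 300 kb stated resolution, and
a requested 40 kb regional resolution is tiled at 40/3 kb spacing.

- Backbone: uniform per-chromosome tiling at the requested spacing,
  starting at spacing/2, at least one probe (the midpoint) per
  chromosome. If the implied count exceeds the tier budget the spacing is
  widened to `ceil(genome_size / budget)` and reported.
- Targeted regions: within-region spacing = resolution/3 with a 3-probe
  per-region minimum; budget overflow is resolved by deterministic
  proportional thinning (keep every k-th probe), degrading the achieved
  resolution uniformly.
- Enhancer tier: per enhancer of length L, `n = max(3, ceil(L / 238))`
  probes at the n evenly spaced interior positions
  `start + floor((j+0.5)·L/n)`. The 238 nt spacing is applied as a
  per-enhancer ceiling rule since the rounding of the published average
  is not defined. With a candidate-position catalogue (emulating a
  validated-probe database), each ideal position snaps to the nearest
  in-feature candidate, ties toward the lower coordinate, candidates
  consumed without replacement.
- Plan assembly: normalization and replicate tiers consume their budgets
  as opaque counts; the filler tier absorbs the residual capacity, drawn
  from a supplied catalogue by seeded sampling without replacement. The
  default capacity of 59,905 usable features is the sum implied by the
  published tier counts (25,000 + 18,000 + 7,790 + 1,262 + 5,000 + 2,853)
  and is configurable. Probes are point positions (midpoints); oligo
  selection, Tm and cross-hybridisation screening are out of scope.

Plan invariants (validated on every assembly): total ≤ capacity, per-tier
placed ≤ budget, no duplicate (tier, chromosome, position), positions
strictly increasing within tier and chromosome, and ≥3 probes per
enhancer.

## Probe-track QC, segmentation and the aberration filter

DLRS (derivative log ratio spread) is computed from consecutive-probe
log2 differences within chromosomes, pooled, as `IQR / (1.349·√2)`; for
i.i.d. Gaussian probe noise of SD σ it estimates σ. The constant 1.349 is
the IQR of a standard normal; the √2 removes the variance doubling of
differencing. It is invariant under constant shifts and never crosses
chromosome boundaries.

Segmentation is a recursive two-cut mean-shift scan: within each segment,
the contiguous probe window maximising the pooled-variance two-sample t
statistic between window and remainder is cut out; cuts are accepted
while |t| ≥ t_threshold (default 6) and the three pieces are recursed.
The edge-anchored window reduces to a plain binary split, so single level
shifts are found too. A plain binary (left-vs-right) split statistic was
rejected during design: for a short interior event the edge-split t is
diluted by the unmodelled step (a 10-probe, log2 = −1 event in a 60-probe
noiseless track peaks at |t| ≈ 3.8) and no threshold both detects such
events and controls false splits; the two-cut scan scores the same event
at t = ∞. Zero-variance windows with a mean offset are exact steps and
split unconditionally. The scan is deterministic; cost is O(n²) per
chromosome, appropriate for the targeted-array track sizes (10³–10⁴
probes) this package addresses. The threshold default of 6 keeps the
familywise false-split rate negligible for tracks of ~10³–10⁴ probes
(under Gaussian noise the maximal |t| over windows concentrates near
√(4·ln n) ≈ 5.5) while leaving ≥5-probe events at ≥3σ with t ≥ 8.

The aberration filter then applies the standard aCGH credibility rules:
keep a segment iff it has ≥3 probes and |mean log2| ≥ DLRS. The amplitude
rule is applied to the absolute mean (deletions have negative means); a
segment with mean exactly 0 has no copy-number direction and is never
aberrant, which also covers the noiseless-track corner where DLRS = 0.
The filter is a pure predicate: idempotent, output ⊆ input.

Annotation records every overlapping feature of the enhancer, known-CNV
and syndrome-region sets and classifies each call with a fixed
precedence: disease-region > known-polymorphic > enhancer-CNV >
uncertain. The precedence order is a package design choice (clinical
interpretability first); all overlaps remain recorded so no information
is lost to the ordering.

## Synthetic-data generator

The generator is the package's stand-in for external enhancer/CNV
downloads and raw array data. Defaults describe a desk-scale study:

| parameter | default | rationale |
|---|---|---|
| genome | 5 × 20 Mb chromosomes | large enough for ~10⁴ intervals, small enough for second-scale runs |
| enhancer count / length | 500, U[800, 2200] bp | matches the ~0.8–2.2 kb span of published enhancer loci |
| CNV length | log-uniform [1 kb, 500 kb] | CNV catalogues are right-skewed over ~2 decades |
| coverage target c | 0.15 | mid-range between published catalogue footprints (0.3%–30%) |
| depletion δ | 1.0 (none) | δ is the experiment's knob |
| probe noise σ | 0.2 | typical aCGH log2 ratio noise; DLRS ≈ σ |
| planted shifts | −1.0 loss, +0.585 gain | log2(1/2), log2(3/2): heterozygous deletion / single-copy duplication |

Enhancers are placed uniformly without overlap (rejection sampling). CNVs
are drawn uniformly — chromosome by length-proportional choice, start
uniform, length log-uniform — and each draw that overlaps any enhancer is
retained with probability δ: δ = 1 is placement blind to enhancers, δ = 0
total exclusion. Sampling continues until the merged footprint reaches c
within ±2% relative tolerance; a draw that would overshoot the band is
redrawn with a capped length, and an unreachable target errors after a
bounded number of draws. Under this thinning mechanism the expected
enhancer base coverage is ≈ δ·c, so the fold statistic estimates δ
directly — the property the recovery tests exploit. When the coverage
target is disabled, exactly `n_cnvs` CNVs are drawn instead.

Probe tracks are Gaussian baselines at the plan's (or uniformly spaced)
positions with planted aberrations added over their probe spans. All
sampling is integer-coordinate and driven by a single scenario seed (the
track stream is decoupled from the feature stream so the same scenario
yields independent features and noise); identical seeds give bit-identical
artifacts.

What the generator does *not* emulate: real CNV length/frequency spectra,
assembly gaps and centromeres, GC and wave artifacts in log2 ratios,
segmental-duplication clustering of CNVs, or allele frequencies. Passing
tests therefore demonstrate correctness of the statistics and the
machinery under the stated generative model, not calibration on real
catalogues — in particular the permutation null inherits the same "any
placement is admissible" assumption the generator uses.

## Problem sizes and numerical choices

The test suite and the acceptance script run simulations at desk scale,
chosen so the full suite completes in a few minutes on one core: 100 Mb
genomes with ~2,500 CNVs for δ-recovery (50 seeds × 4 δ values), 99–199
permutations per null (the add-one empirical p then resolves to 1/100 or
1/200 granularity, sufficient for calibration checks at 120–200
replicates), and 40–100 seeded tracks of ~10³ probes for segmentation
sensitivity. Tolerances in tests follow the statistic's own sampling
error (Monte-Carlo SEs, KS at α = 0.01) rather than fixed percentages.
Floating-point guards: pooled variances are floored at 1e-300 before
division, exact steps promoted to t = ∞, and interval arithmetic is pure
integer.

## Known limitations

- Expected counts use the genome-coverage convention `N·c`, which slightly
  understates the placement-null hit probability for long targets (see
  above); the permutation null is the exact reference when this matters.
- The segmenter assumes piecewise-constant means with homoscedastic
  noise; mosaicism, waves and sex-chromosome normalisation are out of
  scope.
- The designer treats probes as points and does not model probe sequence
  quality; the candidate-catalogue mechanism is the hook for that.
- One merged CNV footprint is compared at a time; joint modelling of
  multiple overlapping catalogues is left to the caller (fit one model
  per cover set, as `figure1_table` expects).
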