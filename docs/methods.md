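# Methods

## The ∆depth scan

`deltadepth` detects large homozygous deletions (and, symmetrically, large
duplications) in a mutant genome by comparing windowed depth-of-coverage
between a wild-type and a mutant whole-genome sequencing sample aligned to
the same reference. The procedure:

1. **Dense depth.** Per-base depth for each sample is read from a
   samtools-depth TSV; positions absent from the table are zero (samtools
   omits them by default), and the fill-zero step is mandatory so window
   means are taken over every base.
2. **Moving average.** Depth is averaged in sliding windows of width *w*
   advanced by step *s* (genome scans default to *w* = 3 Mbp, *s* = 1 Mbp;
   benchmark mode uses a 100:1 *w*/*s* ratio, see below). Trailing windows
   are truncated at the chromosome end rather than dropped, so terminal
   deletions — a common product of chromosome-arm breakage — remain visible.
   A chromosome shorter than one window becomes a single window.
   Truncated windows average over fewer bases and carry up to
   sqrt(w/span)-fold inflated sampling noise, so they are excluded from
   null resampling and exceedance testing (they stay in exported tracks);
   the last full-width window reaches the chromosome end, so terminal
   deletions stay detectable.
3. **Normalization.** Each sample's window values are divided by that
   sample's genome-wide mean window value, putting samples of unequal
   sequencing depth on a common scale where the genome average is 1. A raw
   mode skips this; the empirical null then absorbs the coverage offset.
4. **∆depth.** The per-window difference, wild-type minus mutant. A
   homozygous deletion in the mutant appears as a positive plateau of height
   ≈ 1 (normalized); a duplication as a negative dip.
5. **Resampled null.** One window value is drawn from each sample —
   independently, uniformly with replacement over all genome windows,
   positions *not* paired — and the difference recorded; after 4,000 draws
   the 95th and 99th nearest-rank percentiles become the q95 and q99
   thresholds (5th/1st for duplications). Because the draw is
   cross-positional, systematic window-to-window structure shared by the two
   samples (repeat content, GC, mappability) widens the null but cancels in
   the position-matched ∆depth, so the thresholds are conservative: the
   fraction of unchanged windows exceeding q95 is far below 5%.
6. **Region calls.** Maximal runs of consecutive threshold-exceeding windows
   merge into one call whose footprint is the union of the member window
   spans. Calls carry the peak ∆depth and the mean normalized mutant depth
   over contained windows.
7. **Artifact filter (scan mode).** Repeat pile-ups that fluctuate between
   samples can produce sharp ∆depth spikes. A genuine homozygous deletion
   leaves the mutant near zero depth, so deletion calls whose mean
   normalized mutant depth over contained windows exceeds `max_residual`
   (default 0.2) are set aside as artifacts rather than reported.

### The no-change null and implanted-deletion benchmarks

The q95/q99 thresholds estimate quantiles of ∆depth *under no copy-number
change*. In a real two-sample scan the changed fraction of the genome is
negligible (one multi-megabase deletion in a multi-gigabase genome), so
drawing from all windows is an adequate estimate. In a simulation benchmark
that implants a deletion ladder summing to ~1% of a desk-scale genome, the
deleted windows would otherwise occupy more than the top 1% of the mutant
pool and push q99 above the deletion signal itself. `resample_null`
therefore accepts known change intervals to exclude from the pools, and the
benchmark excludes its truth set. The single-deletion window-size experiment
deliberately *omits* the exclusion to reproduce the quantile-contamination
effect (below).

### Scoring against truth

A truth deletion is detected when the union of calls covers at least 80% of
its span (fractional-overlap semantics as in `bedtools -f 0.80`; "more than
80%" is implemented as ≥ 0.8). A call is a false positive only when it
overlaps no truth deletion at all; partial overlaps below the fraction are
neither true nor false positives. Per replicate, sensitivity is detected
truth / all truth. Specificity is window-level: among windows containing no
deleted base, the fraction whose own ∆depth stayed below the threshold
(equivalently, whose footprint lies inside no called region — merged runs
have no interior non-exceeding windows). Replicate summaries are mean ±
sample (n−1) SD. TP% per length class is detected/introduced × 100 pooled
over replicates; false-positive calls are binned by their own called length,
each bin reported as a percentage of all false positives.

## The depth simulator

The generator emulates the aligned-depth signal of a short-read pipeline
without generating reads: read *starts* are a Poisson process at base rate
coverage/read_length per bp, each read covering `read_length` bases
rightward (clipped at the chromosome end). Inside annotated repeat
intervals the rate is multiplied by the interval's factor, emulating
multi-mapping pile-ups; inside implanted deletions it is multiplied by the
zygosity factor (0 for homozygous deletions — exactly zero interior reads).
This is the read pipeline with a perfect aligner: depth autocorrelation
decays over one read length, genome mean approaches the nominal coverage
outside repeats and deletions, and total expected read count is
coverage × non-deleted length / read_length. Coverage subsampling is
emulated by binomial thinning of per-position depth (each position's depth
becomes Binomial(depth, fraction), positions independent); this reproduces
read-level thinning in expectation and loses only a small amount of
positional correlation, which windows ≫ read length never see.

Repeats in the default layout are short elements (30 bp) scattered uniformly
at 5% density with multipliers drawn from {2, 5, 10}. Many small elements
per window give each window a smooth ~23% mean rate inflation with modest
spread — the regime of a windowed scan over a repeat-rich genome, where the
aligner spreads multi-mappers rather than piling them into single spikes.
Long high-multiplier islands (the sharp artifact spikes the artifact filter
exists for) can be constructed explicitly via `SimLayout` but are not part
of the benchmark geometry.

What the simulator does *not* model: sequence content, base qualities,
GC bias, mapping-quality filtering, and between-sample mapping noise.
The last omission matters for interpreting the benchmark: because the
repeat layout is positionally identical in both simulated samples,
position-matched ∆depth noise is pure read sampling, and measured
specificity saturates at ~1.000 under both thresholds — real aligned data
carries residual multi-mapping noise that produces a small rate (~0.3%) of
q95 exceedances. Passing benchmarks therefore demonstrate the statistical
machinery, not robustness to alignment artifacts.

## Benchmark geometry

The reference design this package benchmarks against is a simulation on
three wheat group-3 chromosomes (~750 Mbp each): one implanted deletion per
length class {1, 10, 100, 300, 500, 700 kbp, 1, 5, 10 Mbp}, 5× coverage,
150 bp reads, a 1 Mbp window with 10 kbp step, 4,000-draw null, 100
replicates. Per-base simulation at 2.2 Gbp per replicate is not desk-scale,
and the design cannot be shrunk by truncating chromosomes alone: the
detection physics is governed by dimensionless ratios — deletion length to
window, window to step, read length to window, and critically the fraction
of windows inside deletions, which must stay below the 1% quantile rank or
the null is contaminated.

The package's default benchmark therefore scales **every length by 1/20**,
preserving all ratios:

| quantity            | full-scale design | benchmark default |
|---------------------|-------------------|-------------------|
| chromosomes         | 3 × ~750 Mbp      | 3 × 30 Mbp        |
| window / step       | 1 Mbp / 10 kbp    | 50 kbp / 500 bp   |
| deletion classes    | 1 kbp … 10 Mbp    | 50 bp … 500 kbp   |
| read length         | 150 bp            | 8 bp              |
| class/window ratios | 0.001 … 10        | 0.001 … 10        |
| fully deleted windows | 0.59% of genome | 0.67% of genome   |

Coverage (5×), the 4,000-draw null, the ≥80% overlap rule, and per-sample
normalization are scale-free and kept as-is. Replicates default to 20
(from 100) to keep the study under ~10 minutes on one CPU; with one
deletion per class per replicate each class still accumulates 20
detection trials. Deletions are placed genome-wide, the chromosome chosen
with probability proportional to length, mutually non-overlapping.

Detection-rate targets are read off at the invariant class/window ratios:
the "100 kbp class" of the full-scale design is the ratio-0.1 class (5 kbp
here), the "1 Mbp class" is the ratio-1.0 class (50 kbp here).

## The window-size effect

With a fixed deletion, enlarging the window beyond the deletion length
degrades detectability. Two mechanisms: the plateau height falls as
deletion/window once the window exceeds the deletion; and when thresholds
are estimated from the same genome without excluding the deletion, a large
window smears the deletion across > 1% of all windows, lifting q99 into the
signal cluster — the unpaired draw adds the wild-type pool's spread on top,
pushing q99 above the matched peak. The package reproduces this with a
single 150 kbp deletion (3× the 50 kbp benchmark window): detection is
complete at windows ≤ 3× the deletion and collapses at a 10× window.

## Co-dominant deletion markers

For genotyping progeny across a called deletion, three primers give one
assay distinguishing all three genotypes: a forward primer upstream of the
deletion (pre), a forward primer inside it (in), and a reverse primer
downstream (post). Wild-type homozygotes amplify in→post (the in-deletion
primer has template); mutant homozygotes amplify pre→post across the
collapsed junction (shorter by the deletion length); heterozygotes show
both bands. Given requested wild-type and mutant product sizes, the layout
solves the two length equations with the post primer anchored half the
mutant product beyond the distal breakpoint, so the junction fragment is
centred on the breakpoint. Coordinates only: primer sequences, melting
temperatures and genome-wide specificity belong to dedicated design tools,
and breakpoints from a windowed scan carry ± one step of uncertainty, which
the CLI reports so primers are placed conservatively.

## Numerical choices and edge cases

- Percentiles are nearest-rank on the empirical resample — reproducible, no
  interpolation ambiguity; q99 ≥ q95 by construction.
- All coordinates are 0-based half-open internally; the depth TSV dialect is
  1-based on input and output; BED/bedGraph outputs are 0-based half-open.
- Window means use float64 cumulative sums; at benchmark sizes (30 Mbp,
  depth ≤ ~10²) the accumulated rounding is ≪ 1e-9 of a window mean.
- Multi-allelic VCF records are skipped with a warning (summaries here do
  not depend on them); indels with length difference > 25 bp are skipped,
  matching the short-indel ceiling of the upstream caller.
- Ts/Tv with zero transversions raises rather than returning infinity.
- Every stochastic operation takes an explicit seed; replicate orchestration
  derives child seeds via `numpy.random.SeedSequence` spawning, so any
  replicate is reproducible in isolation from its logged seed.

## Known limitations

- Depth-level simulation cannot expose alignment-specific failure modes
  (soft-clipping at breakpoints, mapping-quality loss in diverged repeats).
- Heterozygous deletions (zygosity factor 0.5) are generated but the
  detection side is tuned for the homozygous case; the artifact filter's
  0.2 residual ceiling would reject a clean heterozygous call (~0.5).
- Breakpoints are window-resolution; no split-read refinement.
- The specificity band of real aligned data is not reproduced exactly (see
  the mapping-noise note above): the simulator's specificity is ~1.000
  under both thresholds rather than 0.997 under q95.
- The artifact filter assumes calls substantially longer than one window;
  for calls ~2 windows wide the flank windows can dominate the contained-
  window mean.
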