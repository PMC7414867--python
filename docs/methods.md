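# Methods

This note records the conventions, formulas and design choices behind
`hrdscar`: what exactly is counted, how agreement is quantified, what
the synthetic cohort generator does and does not emulate, and the
numerical corner cases.

## Coordinate model

All coordinates are 1-based, fully-closed intervals (the ASCAT segment
convention). Scores and bin grids are restricted to autosomes 1–22 by
default; sex chromosomes are dropped during normalisation. GRCh37
chromosome lengths and centromere intervals (the UCSC gap-table
centromeres, collapsed to one interval per chromosome) are bundled as
TSV assets and are swappable — any consistent centromere table preserves
the score semantics. Bin grids tile each chromosome into
`ceil(length / bin_size)` consecutive bins (final bin partial); at the
default 10 kb this yields 288,113 bins over the GRCh37 autosomes.

A position inside the centromere interval belongs to neither arm.
Normalisation splits centromere-overlapping segments at the centromere
boundaries and discards the in-centromere bases; the chromosome-level
components (NtAI, HRD-LOH) then re-join identical-state pieces across
the centromere gap, so a segment that genuinely spans the centromere is
scored as one segment, while per-arm LST counting uses the split view.

## Scar components

**Normalisation** (applied once before scoring): drop non-autosomes,
split at centromeres, merge adjacent segments with identical
(nMajor, nMinor) and zero gap. Scoring is invariant under splitting any
segment into same-state pieces (property-tested), and normalisation is
idempotent. Gaps between segments (unsegmented regions) are permitted
and preserved.

**NtAI.** A segment counts when it is the first or last segment of its
chromosome, has nMajor ≠ nMinor, does not contain bases on both sides of
the centromere, is not the chromosome's only segment, and reaches
`ntai_min_len` (default 0). Telomere-touching is defined on the profile
(first/last segment), not on raw coordinates: real caller output rarely
reaches literal base 1, and the concept is about the profiled chromosome
ends. Whether the original scoring scripts applied a minimum NtAI
segment length is not documented anywhere we could verify; the default
of 0 is therefore exposed as a parameter rather than guessed.

**HRD-LOH.** LOH state is nMinor = 0 with nMajor ≥ 1; homozygous
deletions (0+0) terminate a region by default (`loh_allow_homdel`
flips this), since LOH requires a retained allele. Consecutive LOH
segments with zero gap merge into one region regardless of nMajor. A
region counts when strictly longer than 15 Mb and not spanning the
chromosome's entire segmented extent. Runs are not merged across
non-LOH interruptions or across coverage gaps.

**LST.** Per chromosome arm: (1) iteratively remove segments shorter
than 3 Mb; when a removal makes two identical-state neighbours adjacent
they merge into one segment spanning the removed region; (2) count
adjacent pairs with different states, both flanks ≥ 10 Mb, inter-flank
gap ≤ 3 Mb. Removal order matters in degenerate configurations, so it
is fixed deterministically: removals that enable a same-state merge are
taken first (shortest, then leftmost), then remaining short segments
(shortest, then leftmost). Prioritising merge-enabling removals restores
a large flank interrupted by one short noise segment exactly, instead of
letting neighbouring removals cascade into a coverage hole wider than
the 3 Mb gap tolerance. No ploidy-specific LST cutoff is applied: the
summed score is compared against the fixed threshold of 42, with ties
classified deficient (≥ 42).

All five constants (15 Mb, 10 Mb, 3 Mb smoothing, 3 Mb gap, threshold
42) live in `ScoringParams`; alternative conventions are one
configuration away. Component contributions are reported as
`100 · component / score`, all zero for a zero score.

## QC metrics

dLRS is the sample standard deviation of Log2 differences between
genomically adjacent probes divided by √2 (the derivative form, which
estimates the per-probe noise sd for white noise); a `plain_sd` flag
computes the plain sd of the Log2 values instead, for the literal
"standard deviation of Log2 ratios" reading. MAPD is the median absolute
adjacent-probe Log2 difference. Differences never span chromosome
boundaries.

Binned comparisons reduce each platform's Log2 signal to a common grid:
per bin the median of all values mapping to it (midpoint convention for
ties); in segmented mode a segment contributes its single Log2 value
once per overlapped bin, not length-weighted. When segment Log2 values
are not supplied they are derived from the copy state as
`log2(total / ploidy)` with totals floored at 0.5 copies to keep the
logarithm finite at homozygous deletions. The cross-platform deviation
is the median absolute per-bin difference of segmented Log2; the
cross-platform correlation is the Spearman coefficient of binned probe
Log2. Bins without data are excluded pairwise, never imputed; constant
inputs make the correlation undefined (reported as NaN with a warning).

## Agreement statistics

Direction conventions: the sequencing platform is the explanatory
variable in regressions, and Bland-Altman differences are WGS − array.

* **Bland-Altman**: bias = mean(d), limits = bias ± 1.96·sd(d);
  CI of the bias uses t(0.975, n−1)·sd/√n, CI of each limit uses
  SE = sd·√(3/n) (the convention of the standard R implementation of
  these plots). The within-limits fraction of a Gaussian difference
  sample is ≈ 95% by construction (verified on 10,000 simulated pairs).
* **ICC(3,1)**: two-way mixed, single measure, consistency form,
  (MS_subjects − MS_error) / (MS_subjects + MS_error) for two raters;
  a fixed platform offset does not reduce it. Cross-checked in tests
  against an explicit ANOVA decomposition and against pingouin's
  ICC(C,1).
* **Fleiss' kappa** for the two-rater dichotomous HR call (equivalent to
  Scott's pi), with the classic large-sample null standard error and a
  two-sided z-test p-value. Undefined (NaN) when only one category
  occurs. Cross-checked against exhaustive 2×2 contingency enumeration
  and statsmodels.
* **Contribution comparisons**: platform-paired mode uses the Wilcoxon
  signed-rank test per component (exact null below 5 informative pairs);
  HR-status mode compares deficient vs proficient samples *within* one
  platform — those groups are unpaired, so a rank-sum (Mann-Whitney)
  test is used there; a signed-rank test is not applicable to unpaired
  groups even though method-comparison reports sometimes label both the
  same way.
* **Distribution comparisons**: two-sample two-sided Kolmogorov-Smirnov
  with asymptotic p.

No multiple-testing correction is applied anywhere; all p-values are
raw.

## Synthetic paired cohorts

The generator stands in for a paired array/WGS tumour cohort whose real
counterpart is controlled-access. It emulates exactly the quantities the
scoring consumes — the segmentation and its platform-dependent noise —
and nothing below them.

**Truth profiles** start from an all-1+1 diploid autosomal genome and
receive Poisson numbers of three event types: interstitial LOH regions
(1+0, length U(20, 45) Mb), telomeric AI events (2+1 or 3+1, U(5, 30)
Mb, confined to one arm), and interstitial state switches ((2,2), (2,1)
or (3,1), U(14, 28) Mb). Placement keeps every event ≥ 13 Mb from arm
boundaries and from other events. These margins comfortably exceed the
15/10/3 Mb qualifying cutoffs, which buys two guarantees: injected
counts equal the truth profile's component scores exactly (each LOH
event = 1 HRD-LOH + 2 LST, each switch = 2 LST, each telomeric AI
event = 1 NtAI plus 1 LST when ≥ 10 Mb), and sub-3 Mb view
perturbations cannot flip a qualifying region across a cutoff. Archetype
means (deficient: 12 telomeric AI, 8 LOH, 10 switches; proficient:
2/1/2) put expected scores near 65 and 11 — clearly on either side of
the threshold of 42, mirroring the clearly-deficient vs
clearly-proficient reference cases such comparisons are anchored on.
An event that cannot be placed after 100 attempts is skipped and the
recorded truth shrinks accordingly.

**Platform views** apply three mechanisms: (1) each event drops out with
probability `p_miss_event`; (2) each breakpoint jitters by
N(0, `breakpoint_jitter_sd`), with telomeric ends anchored and ordering
preserved by clamping; (3) spurious breakpoints appear as a Poisson
process along the genome (`p_spurious_breakpoint` per 100 Mb), each
perturbing the allele state on one side of the breakpoint — one extra
major-allele copy over ≤ 3 Mb, clamped at chromosome ends. The clamping
matters: a false boundary near a telomere leaves a short terminal
imbalanced segment, which is precisely how segmentation noise inflates
NtAI (the minimum NtAI length is 0); clusters of spurious breakpoints
can also merge into > 3 Mb artifacts that survive smoothing and perturb
LST either way. The net effect of the shallow-coverage presets is a mean
upward score shift, matching the direction observed when real WGS is
downsampled. Event dropout is modelled only for the array preset
(arrays can miss small events between probes); the WGS tiers model
shallower coverage purely as noise, since wholesale caller failures on
low-coverage samples are out of scope.

Shipped presets (`array`, `wgs70x`, `wgs30x`, `wgs15x`, `wgs10x`) fix
probe spacing at 1.6 kb (≈ 1.8 M probes genome-wide, the density of both
the array and the WGS SNP panels) and order spurious-breakpoint rate and
Log2 noise monotonically with decreasing nominal coverage
(0.05 → 2.0 per 100 Mb; 0.12 → 0.32 Log2 sd). **Probe tracks** sample a
view every `probe_spacing` bp: Log2 = log2(total/2) + Gaussian noise,
BAF drawn around minor/total, randomly reflected about 0.5 (allele
labels are arbitrary) and clamped to [0, 1].

What the generator does **not** emulate: purity/ploidy mis-estimation,
subclonal (non-integer) copy numbers, GC-bias and mappability structure,
probe-density variation, read-level effects, and caller failures.
Passing recovery and concordance tests therefore demonstrates the
correctness of the scoring and agreement machinery under a controlled
noise model — not the field performance of any particular caller on
real shallow sequencing.

Determinism: one global integer seed; every sample × platform ×
purpose substream is derived via a seed sequence over (seed, sample
index, CRC32 of the stream label), so outputs are bit-reproducible and
adding a platform does not shift other platforms' streams.

## Problem sizes and numerical choices

The test suite exercises the scoring against an independent brute-force
rule enumerator on 1,000 random ≤ 12-segment-per-chromosome profiles,
and the synthetic end-to-end checks use 20 replicate paired cohorts of
67 samples (the size of the motivating study cohort) with a 50%
deficient fraction; the whole suite runs in well under a minute of CPU.
`scripts/acceptance.py` uses the same sizes.

Numerical conventions not covered above: medians use the midpoint
convention; sample standard deviations use ddof = 1; copy numbers are
validated as integers (optional half-away-from-zero rounding for
subclonal input); swapped allele order (nMinor > nMajor) is
canonicalised with a warning rather than rejected; overlapping or
unsorted segment rows are rejected with file row numbers. Score tables
and JSON reports serialise floats at full precision and round-trip
exactly.

## Known limitations

* The scar-component literature contains several variant conventions
  (ploidy-corrected LST thresholds, minimum NtAI lengths, LOH-run
  bridging rules). `hrdscar` implements one documented, parameterised
  convention; when comparing against numbers produced by another
  implementation, align `ScoringParams` first.
* Fleiss-kappa inference uses the large-sample z-test only; exact
  small-sample inference is out of scope.
* The QC module consumes caller-provided or simulated Log2/BAF tracks;
  it does not normalise raw array intensities or compute coverage
  metrics from alignments.
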