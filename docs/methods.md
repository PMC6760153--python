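# Methods

This note documents the models, rules, and numerical choices behind
`chronopheno`, and what the synthetic-data validation does and does not
establish.

## Data model

Wheel-running activity is stored as integer revolutions per acquisition bin
(5 min by default), anchored to a clock time `t0`; counts are integers so
rebinning is exactly conservative. Missing bins are an error unless
`zero_fill` is requested: fragmentation statistics (IV, naps) are corrupted
by silent imputation, so the default refuses gaps. The experiment structure
(LD/DD segments, treatment windows) lives in a phase plan of contiguous
whole-day segments; ZT0 is lights-on of an LD segment, and in DD circadian
time is anchored to the animal's own activity onset with onset = CT12 (the
nocturnal convention).

## Chi-squared periodogram

For a candidate period of `p` bins, the first `K·p` bins are folded into `p`
columns and

    Qp = K·N′ · Σ_h (M_h − M̄)² / Σ_i (x_i − M̄)²,    N′ = K·p,

with `M_h` the column means. Under the no-rhythm null Qp is asymptotically
χ²(p−1). Two finite-sample choices matter at the ~10 cycles a typical DD
segment provides:

1. **Common cycle count.** The textbook fold uses `K = floor(N/p)` per
   candidate. That hands one extra complete cycle — and hence systematically
   higher Qp — to periods that exactly divide the record (24.0 h in an
   11-day record of 5-min bins), and the peak aliases onto them. All
   candidates therefore use the same `K = floor(N/p_max)`.
2. **Exact significance line.** Qp = N′·SSB/SST is bounded by N′, so its
   null tail is lighter than χ²; at the Bonferroni-corrected working level
   (α/m ≈ 5·10⁻⁴ over the m ≈ 97-candidate grid) the χ² quantile is
   noticeably conservative (family-wise rate ~0.01 instead of 0.05).
   Under Gaussian errors the exact null is Qp/N′ ~ Beta((p−1)/2, (N′−p)/2)
   (equivalently an F form), and the significance line uses that quantile.
   Measured family-wise rate on rhythm-free Poisson records: 0.04–0.06.

The peak is the candidate maximizing Qp − line; its excess is reported as the
periodogram amplitude (the activity-profile amplitude is reported separately,
since which of the two "amplitude" denotes in batch actigraphy software is
ambiguous). Candidates are integer bin counts only — Qp is defined for
integer folds — so τ is quantized to the bin width (0.083 h at 5-min bins).
Degenerate (zero-variance) records are rejected.

## IS and IV

Interdaily stability and intradaily variability follow the conventional
(van Someren) definitions on hourly-rebinned counts over complete days:

    IS = N·Σ_h (x̄_h − x̄)² / (24·Σ_i (x_i − x̄)²)     ∈ [0, 1]
    IV = N·Σ_{i≥2} (x_i − x_{i−1})² / ((N−1)·Σ_i (x_i − x̄)²)

IS = 1 exactly for day-repeating input and ≈ 1/n_days for structureless
noise; IV ≈ 2(1−cos(2π/24)) ≈ 0.068 for an hourly-sampled 24-h sinusoid
(exact up to an O(1/N) boundary term), 2 for white noise, 4 for a strictly
alternating sequence. Some actigraphy literature swaps the words
"stability"/"variability" between the two formulas; the function names here
are unambiguous about which formula is computed.

## Onsets, sleep offsets, naps and bouts

**Onsets.** Per cycle of an assumed period τ, the onset is the time
maximizing the contrast between mean smoothed activity in the following 6 h
and the preceding 6 h (a −1/+1 step template on 1-h-smoothed bins; ties to
the earliest time). Commercial onset detectors are unpublished; template
matching is the standard surrogate. With the generator's 1-h half-cosine
activity ramp the template peaks ~half a ramp after the true ramp start, a
systematic ≤0.5 h delay that cancels in within-subject contrasts (which is
how onsets are used downstream). Cycles without activity are skipped with a
warning.

**Sleep offsets.** Per cycle, the offset is the start of the first run of at
least 3 consecutive hours, searched forward from the cycle's activity onset,
in each of which hourly counts fall below 20% of the mean hourly count of the
active phase. The 20% reference is computed per analyzed segment (baseline
vs treatment), not globally, because offsets are compared within phases. The
active phase is the lights-off window (from the phase plan) in LD and the
12 h from the detected onset in DD. Cycles with no qualifying run yield no
offset. Whether the original search began at onset or lights-off is not
documented; starting at onset is the default and the two coincide for an
entrained animal.

**Naps/bouts.** On 30-min rebinned counts, a nap is a maximal run of ≥2
consecutive zero-count bins inside the active phase; a bout is a maximal run
of ≥2 consecutive nonzero bins in the rest phase. "Without activity" is
strict zero, not a low threshold — the defining contrast is with "with
activity". Runs may not bridge gaps between cycles' windows.

## Behavioral scoring

Alternation: all overlapping windows of 3 consecutive (deduplicated) arm
entries; correct = all three arms distinct; with no immediate re-entry the
chance level is 50% (2 available arms, 1 completes the triad). Freezing and
swim immobility use maximal still runs of ≥2 s; a run straddling the 2-min
forced-swim cutoff contributes only its post-cutoff part. Whether the
original swim scoring also used a 2-s threshold is not stated (it is stated
for freezing); 2 s is the default and configurable. Zone metrics count label
changes as crossings. All scorers are exact run-length computations, tested
against independent brute-force oracles on randomized inputs.

## Histology quantification

The plaque threshold is mean + k·SD (k = 1 by default) of the cropped
section; statistics are computed on the cropped ROI, matching the practice
of cropping before thresholding. The binary mask gets a 1-px morphological
opening (removes speckle from the ~16% of noise pixels any mean+1SD
threshold admits) and hole filling before 8-connected labeling. "Well
circumscribed" is operationalized as circularity 4π·area/perimeter² ≥ 0.4
and area ≥ 50 μm² — no numeric shape rule is documented anywhere, so both
are explicit, configurable parameters chosen to reject streaks and edges
while keeping disc- and Gaussian-profile objects. Plaque size is the
equivalent circular diameter 2·√(area/π) in μm (the only way an area yields
a size in μm); per subject, the mean of the 3 largest plaques, ties broken
by row-major centroid order. Percent area is the fraction of pixels above
the same threshold — invariant under positive affine intensity rescaling.
8-bit conversion is a linear min–max rescale (constant images map to 0) and
preserves pixel rank order, so thresholding before or after conversion
selects the same pixels up to quantization.

## Group statistics

Fixed per-metric order: 2-SD outlier screen → Shapiro-Wilk per group →
Levene (center = mean) → omnibus → Tukey HSD only if the omnibus is
significant at 0.05. The outlier screen is single-pass with full-group mean
and **population** SD and an inclusive boundary: a lone outlier among n
points can reach at most √(n−1) population SDs, exactly 2 at n = 5, so a
sample-SD or strict-inequality variant could never exclude anything from
small groups. Normality failures flag the metric but do not switch the
analysis (no nonparametric fallback is invented).

The mixed design (between: genotype, dose; within: 2-level phase) is
computed by exact decomposition: a factorial ANOVA on per-subject phase
means carries the between-subject effects (error = subjects within groups),
and a factorial ANOVA on per-subject phase differences carries the
within-subject effects, its intercept testing the phase main effect (error =
phase × subject). For two within levels this is algebraically identical to
the classical mixed ANOVA and sphericity is moot. Factors are Sum-coded and
interactions tested Type-III; in balanced designs this coincides with every
other convention (and with `pingouin.mixed_anova`, used as an independent
cross-check for one-between designs), and all scaled sums of squares add to
the total SS exactly. Under imbalance the phase effect is the unweighted
(Type-III) one. Subjects missing a phase are dropped with a warning. Tukey
uses the studentized range with the Kramer correction for unequal n (scipy).

## Synthetic data: what it emulates

The actogram generator draws Poisson counts around a rate profile: a plateau
of `active_rate` counts/min for `active_fraction` of each τ-cycle with 1-h
half-cosine edge ramps (step edges would make ±1-bin onset/offset truths
arbitrary), `rest_rate` elsewhere; per-cycle Gaussian onset jitter;
continuous exponential amplitude decay (a day-stepped decay would inject a
spurious exact-24 h periodogram component); naps as strictly-zero runs
aligned to the 30-min grid and confined to the plateau (so every injected
nap is scoreable truth); multiplicative masking during lights-on in LD.
Counts are Poisson because wheel counts are event counts — integer, with
mean-variance coupling.

Default study-structure preset: 2 genotypes × 3 doses, n = 8/group,
11-day baseline DD + 12-day treatment DD; group-mean periods 23.69 h
(APP-PS1) vs 23.95 h (nTg); treatment adds ~0.3 h at both doses in APP-PS1
and at the high dose in nTg; treated-phase activity retains 39% (APP-PS1) or
57% (nTg) of baseline; the high dose extends the APP-PS1 active phase by
2.5 h (the sleep-offset delay); APP-PS1 animals nap about twice as often,
and the high dose halves nap frequency while lengthening naps. These values
are generator inputs describing the emulated study, not reproduction
targets — the original per-animal recordings are not public. Quantities the
study never reports were set once to field-realistic values: between-animal
τ SD 0.15 h, ~15% lognormal spread in running rates, 0.25 h onset jitter,
30 counts/min plateau rate against a 0.3 counts/min rest rate.

What passing tests show: the estimators are calibrated and accurate **on
data with the assumed structure** (Poisson noise, plateau-shaped activity,
strict-zero naps, disc-like plaques on Gaussian background). Real records
add non-Poisson overdispersion, waveform drift, wheel-hardware dropouts,
ragged plaque morphologies and uneven illumination; the simulators do not
model those, so the validation bounds estimator error, not biological
measurement error.

## Problem sizes and numerics

Validation sizes (chosen so the whole suite re-runs comfortably on one CPU):
period recovery over 200 seeded records, null calibration over 500
rhythm-free records, 1000 random inputs per scorer-oracle check, 200
pure-noise images, 500 replicates per statistical-test calibration, 100
cohorts for end-to-end power. Monte-Carlo assertions use ±2–3 standard-error
bands. The IV sinusoid closed form is checked at 120 000 hourly samples and
amplitude 10⁵ so that integer quantization and the O(1/N) boundary term both
sit below the 10⁻⁶ tolerance. Degenerate inputs (zero variance, empty
groups, single-phase subjects) raise typed errors rather than NaNs.

## Known limitations

- τ is grid-quantized to the acquisition bin; no sub-bin interpolation.
- Onset detection carries the ~half-ramp template delay described above.
- The periodogram's exact Beta null assumes Gaussian errors; for very low
  Poisson rates (< ~5 counts/bin) the far-tail calibration degrades.
- Histology assumes single-channel, already-cropped ROIs; no registration,
  colocalization, or illumination correction.
- The statistics module implements exactly the study's pipeline; it is not a
  general mixed-model engine (no >2-level within factors, no sphericity
  corrections, no lme-style random effects).
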