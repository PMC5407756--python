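# Methods

## Signal model and pre-processing

A recording is a triaxial acceleration series sampled at a fixed rate
(default 200 Hz) while the subject performs three consecutive TUG trials
separated by quiet rest.  Units are deliberately uninterpreted (counts,
g, m/s² are all acceptable): every feature is either scale-covariant or
compared across subjects recorded identically, so only the common scale
matters.

Because the belt-worn sensor's attitude is arbitrary, analysis uses the
magnitude `s(t) = sqrt(x^2 + y^2 + z^2)`, which is exactly invariant
under any fixed rotation, permutation or sign flip of the axes.

The low-pass filter is a Butterworth of configurable order (default 4 —
conventional in gait work) applied forward–backward (`sosfiltfilt`) so
that no stage shifts trial boundaries in time.  The default cutoff of
100 Hz is the acquisition-side anti-aliasing convention; at a 200 Hz
sampling rate it equals Nyquist, where a digital low-pass degenerates,
so the operation becomes an identity and logs a notice.  Meaningful
in-band smoothing (e.g. 15–20 Hz for gait) is available through the same
parameter.

## Spectra

`power_spectrum` returns the one-sided squared modulus of the DFT with
per-sample normalisation, `S(w) = |F(s)/n|^2`.  The normalisation is a
deliberate design choice: with the raw `|F(s)|^2` convention, peak powers
grow with the square of trial length, so subjects with longer TUG-C
trials would appear to have "stronger" harmonics for duration reasons
alone, and typical per-bin powers would far exceed 1, which inverts the
relation between spectral richness and the entropy feature below.  With
per-sample normalisation a bin-aligned sinusoid of amplitude A carries
power (A/2)^2 regardless of duration.  Parseval's identity holds in the
matching form: the one-sided power, with interior bins doubled, sums to
`sum((s - mean)^2) / n`.

The mean is subtracted before the transform by default (`demean=True`)
so that the static gravity component does not occupy the DC bin; peak
searches and the entropy sum skip DC whenever demeaning was applied.
No zero-padding is used: segments keep native length, and frequency
resolution therefore varies with trial duration.

## Features

Per source signal (whole concatenation `s`, trials `t`, `m`, `c`):

- **PSE** `= -sum_w S(w) log(S(w) + eps)`, natural log, `eps = 1e-3`
  guarding `log(0)`.  Computed on the spectrum as given, without
  renormalising S to a probability distribution: the feature is meant to
  mix spectral shape with the amount of acceleration energy, which a
  normalised Shannon entropy would discard.  The log base only rescales
  the feature uniformly across subjects.
- **PSPF/PSP/WPSP 1–3** by successive argmax with a ±0.25 Hz exclusion
  band around each found peak.  Excluding only the single previously
  found bin would return the immediate neighbour of the same spectral
  lobe; the band makes the second and third returned peaks genuinely
  distinct structures (in gait terms, higher harmonics).  Ties break
  toward the lower frequency.  0.25 Hz corresponds to ±2–3 bins at
  typical 10–15 s trial lengths.

The 40-element vector is ordered source-major (`s, t, m, c`), feature
minor (PSE, PSPF 1–3, PSP 1–3, WPSP 1–3), serialised as `pse__c`,
`wpsp_2_c`, etc.

Distance features are absolute differences of a scalar feature between
two sources.  All ten scalars are emitted per pair (60 values over the
default six pairs, which add (m, c) to the five whole/first-trial
comparisons; a literal five-pair set is available).  Where a family-level
distance is quoted (d_PSE, d_PSP, d_PSPF, d_WPSP), it is the
first-component one (`d_psp_1_s_c`, ...), since the multi-component
families are otherwise ambiguous.

## Segmentation

The detector works on the mean-subtracted magnitude: a rolling median
(window k, default 0.5 s) suppresses within-trial oscillation, then the
rectified deviation |u| is summed over half-second windows and compared
with a data-driven threshold `c * mean(|u|) * window_samples`.  The
signed sum of a mean-free signal is near zero over any window, so the
rectified statistic is the reading under which thresholding can separate
activity from rest; the signed variant is retained behind
`literal_sum=True` for auditability.

The threshold scale defaults to `c = 0.5`.  Rest-level |u| is on the
order of a few percent of burst-level |u|, so the overall mean sits
between the two; taking half of it places the threshold inside the wide
empty band for any activity fraction up to ~90%, whereas `c = 1` lies
inside the burst-level distribution once activity occupies the majority
of the recording and fragments trials.

Post-processing merges candidates separated by under 1 s and discards
candidates shorter than 2 s (true TUG trials last upwards of ~9 s, so
the margin is large), then refines each boundary at sample resolution:
within one window of the coarse boundary, the segment extends to the
first/last sample whose smoothed |u| (0.1 s boxcar) exceeds
`0.15 * mean(|u|)`.  The refinement threshold is deliberately low — its
job is to find where activity decays into the rest floor, not to
re-classify — and bounds the boundary error by the median filter's edge
spill (~k/2) rather than the half-second window grid.  Exactly three
surviving segments are named TUG, TUG-M, TUG-C in temporal order; any
other count raises `SegmentationFailure` carrying the candidates, and a
manual-override path (`apply_manual_segments`, or an overrides CSV in
the pipeline) substitutes hand-picked intervals, mirroring how the
occasional recording must be corrected by eye.

Sample intervals are 0-based and half-open.  "Whole-signal" features use
the concatenation of the three labelled segments; rest intervals are
ignored.

## Cohort statistics

- **Screening**: two-sided Mann-Whitney U per feature, exact
  distribution when both groups have ≤ 20 subjects and the pooled values
  are tie-free (the 18 + 18 design sits inside that range), otherwise
  the tie-corrected normal approximation.  Significance is flagged at
  raw p ≤ 0.05; a Benjamini–Hochberg q-value is reported alongside for
  transparency but is not used for selection, matching the screening
  character of the analysis.
- **Fusion**: min-max normalisation of each selected feature over the
  cohort followed by the per-subject mean.  Zero-range features are
  excluded with a warning.  The fused variable is invariant to positive
  affine transforms of any component.
- **ROC**: empirical curve with faller positive; orientation auto-flips
  when the raw AUC is below 0.5 (recorded in the result; permutation
  nulls should use `orient="fixed"`, since flipping every replicate
  biases the null mean above 0.5).  The operating point is the
  equal-error-rate threshold — the point minimising
  |sensitivity − specificity|, ties toward higher sensitivity — because
  the headline operating characteristics are sensitivity = specificity
  pairs.  f1 is the harmonic mean of precision and sensitivity there.
  The probability cut-off comes from a univariate logistic fit of label
  on score (near-unregularised, C = 1e6; under complete separation the
  fit saturates and the probability cut-off approaches 0 or 1, which is
  the correct limit), always reported next to the raw value cut-off so
  the mapping is auditable.  The AUC CI is a stratified nonparametric
  bootstrap of subjects (default 2000 replicates, percentile interval,
  fixed seed); DeLong-style intervals could be swapped in without
  touching the pipeline.

## Synthetic data

`generate_recording` emits rest–burst–rest structure: a gravity baseline
(1.0) with Gaussian rest noise (SD 0.01), and per-trial bursts adding
three harmonics of a 1.4 Hz fundamental (a typical elderly step rate)
plus larger noise (SD 0.05), at default trial durations 10, 11 and 14 s
(near the reference cohort's TUG, TUG-M and TUG-C means) with 5 s gaps.
The scalar magnitude is distributed over the axes through a random fixed
unit orientation, so axis fusion is exercised end-to-end against an
arbitrary sensor attitude.  Group contrast enters through the second and
third harmonic amplitudes (fallers 0.06/0.03, non-fallers 0.14/0.09, in
baseline units, fundamental 0.30 for both) and not through durations,
mirroring the empirical pattern that test seconds do not discriminate
while spectral content does.  Cohort generation jitters each subject's
amplitudes lognormally (σ = 0.25) and draws durations/gaps per subject,
so groups overlap as real cohorts do.  All randomness flows from one
integer seed through spawned per-subject streams.

`generate_feature_cohort` skips the signal level entirely and draws
per-group Gaussian feature values; its default parameters are the group
mean ± SD statistics of the discriminative features reported for the
36-subject reference cohort (`REFERENCE_GROUP_STATS`), including the
fused-feature and fused-distance rows.

What the synthetic data do **not** emulate: sub-phases of a TUG
(sit-to-stand, turning), step-level timing variability, non-stationary
harmonics, sensor drift, or any coupling between features beyond an
optional user-supplied Gaussian correlation.  Passing tests on synthetic
cohorts therefore demonstrate that the pipeline recovers structure it
was pointed at — segment schedules, injected spectral contrast, stated
group distributions — not that the features would discriminate in a new
clinical population.

## Problem sizes and determinism

The default test suite and the acceptance script use desk-scale problems
chosen as the package's own verification sizes: 100-seed segmentation
Monte Carlos, 500-replicate 18-vs-18 cohort simulations, 1000-label
permutations, brute-force DFT oracles up to 64 samples.  The end-to-end
pipeline on a 36-subject synthetic cohort completes in well under a
minute on one CPU.  Every stochastic step takes an explicit seed, stage
outputs are pure functions of inputs plus configuration, and a pipeline
rerun with the same config and seed reproduces its CSV outputs
byte-for-byte.

## Known limitations

- The segmentation detector assumes exactly three activity bursts and
  rest that is genuinely quiet; pacing, fidgeting or missing rest gaps
  push recordings onto the manual-override path.
- With 18 subjects per group the exact Mann-Whitney p-values are
  fine-grained but single-cohort AUC estimates remain noisy (±0.07 SD);
  headline numbers should be read with their bootstrap intervals.
- PSE depends on the common amplitude scale of the cohort's recordings
  (by design); cohorts mixing sensors with different gains must be
  rescaled before comparison.
- The probability cut-off is as good as the logistic score→probability
  map; rank-based alternatives would change it (but not AUC, sensitivity
  or specificity).
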