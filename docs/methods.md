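# Methods

This note records the models, parameter choices and numerical decisions
behind ictalpy, in the package's own words: what each stage assumes, which
knobs matter, what the synthetic-data generator does and does not emulate,
and where the design was genuinely open.

## Seizure annotation

Spike-wave discharges (SWDs) are detected on the 1–250 Hz band-passed EEG.
Candidate spikes are positive peaks exceeding `amp_factor` (default 1.5)
times a rolling baseline envelope. The envelope is the rolling 95th
percentile of |signal − median|, computed in 1-s chunks, smoothed over 10 s,
and recomputed once with detected spikes excluded (two passes). The 95th
percentile — the *visible excursion* of the background — rather than a
MAD/SD envelope is deliberate: a human marker judging "1.5× baseline"
compares a spike against the trace envelope, and 1.5× an SD-like envelope
(~1.5σ) is crossed constantly by Gaussian-like background, making the
criterion vacuous.

Suprathreshold peaks are grouped into bursts when inter-spike intervals fall
within [1/9 − 0.03, 1/5 + 0.06] s; a gap up to twice the upper tolerance
bridges one missing spike. Within each candidate burst, sub-dominant peaks
(height below half the burst's 90th-percentile peak height) are pruned —
SWD spikes dominate the local height distribution, background peaks do not —
then near-duplicates closer than the 9-Hz minimum interval are dropped
(keeping the taller) and edge peaks whose interval to the burst exceeds
1.5× the median ISI are trimmed. A burst is accepted iff it has ≥ 4 spikes,
lasts ≥ 0.5 s, has a mean spike frequency in [5, 9] Hz, and is regular
(ISI coefficient of variation ≤ 0.3 — the operationalization of "regular
burst structure"). Onset and offset are the first and last spike peaks.

Automated detection is a stand-in for expert visual marking; curated
annotations can be supplied from CSV, bypassing it. On the simulator the
detector recovers ~98% of planted bursts with onset/offset errors of a few
milliseconds and no false bursts surviving curation.

Curation (`filter_seizures`) removes seizures shorter than 1.5 s, both
members of any pair with an offset-to-onset gap under 6 s (the gap
convention is a config choice; the source text does not say whether 6 s is
onset-to-onset), and seizures whose recording-edge flank is under 1.5 s.
The operation is idempotent.

A frame is ictal iff its midpoint time lies inside an accepted seizure.
Frames acquired during locomotion (default threshold 1 cm/s; no published
value exists) are excluded from *both* states.

## ΔF/F extraction

Per ROI: (1) drift/bleaching removal at 0.1 Hz, implemented as subtraction
of a rolling-median low-pass with window 1/cutoff = 10 s. A linear
(Butterworth) high-pass at the same cutoff undershoots after every calcium
transient; those undershoots contaminate the bottom-decile baseline and
inflate the noise estimate ~3-fold, which in turn lifts the apparent noise
floor inside suppressed epochs — the median tracker removes the same slow
drift without ringing. (2) Baseline F(t) = mean of the
max(4, ⌊0.1·n⌋) smallest samples within t ± 20 s (window truncated at the
edges; exact, matched against a brute-force oracle to 1e-9), and
ΔF/F = (F₀ − F)/F, stored in percent. (3) A final re-zeroing of each trace
at its noise mode (iterative sigma-clipped median): the bottom-decile
baseline by construction sits ~1.75 noise-SD below the noise mean, so
without recentering the noise floor of ΔF/F is centered *above* zero, the
zero-mean half-Gaussian noise model below never fires, and the quiet rule
becomes unreachable at any noise level.

Denoising fits the negative samples as the lower half of a zero-mean
Gaussian (maximum-likelihood σ² = mean of squared negatives — equivalent to
a half-normal fit and free of the bin-width sensitivity of histogram
fitting; fewer than 30 negatives falls back to a robust full-trace SD with
a warning) and zeroes every sample below +0.5σ. On pure noise this removes
Φ(0.5) ≈ 69.1% of samples and leaves a mean of φ(0.5)·σ ≈ 0.35σ — both
verified against the closed form. σ on busy cells is intentionally the
paper-style estimate from negative data points and runs above the
instrument noise (signal gaps dip below the local median); this only makes
the removal cut more conservative.

Quiet rule: an ROI is quiet iff its summed *fractional* ΔF/F per minute
falls below 6 (GCaMP6M) or 22.5 (GCaMP6S). The unit is a deliberate
interpretation: in percent units an active neuron sums to thousands per
minute and even the post-denoise noise floor sums to hundreds, so
thresholds of 6/22.5 would never fire; in fractional units the noise floor
sums to ~2/min and a typical active neuron to ~50/min, bracketing the
thresholds sensibly. Values are still *stored and serialized* in percent.

ROI segmentation from a mean image (optional; ROIs are usually supplied)
computes intensity profiles along 48 polar rays per seed; the boundary per
ray is the outer end of the contiguous run, starting at the profile
maximum, that stays above background + 50% of the peak elevation (the
half-maximum edge). Seeds on background are flagged unsegmentable.

## Classification

Non-quiet ROIs are labelled by a two-sided Wilcoxon rank-sum
(Mann–Whitney, tie-corrected normal approximation) between all ictal and
all interictal activity at α = 0.05/(number of non-quiet ROIs). The sample
unit is a 2-s bin mean of each state's concatenated frames. Binning is a
calibration necessity, not a convenience: individual frames are
autocorrelated over the indicator decay (~0.6 s), and testing frames
directly labels ~19% of *unmodulated* simulated ROIs non-neutral after
Bonferroni; at 2-s bins the false-positive rate is ≈ 0, while planted
modulations of ∓0.8/+1.5 at 20 seizures are still recovered essentially
perfectly. The 2-s unit is the same one the windowed re-classification
uses. Direction (ictal-low vs ictal-high) follows the sign of the state
mean difference.

## Participation profiles

Per ROI and seizure, mean deviation from the ROI's overall ΔF/F
(Δ(ΔF/F)) is computed in 30 bins of 0.5 s — onset window −10…+5 s, offset
window −5…+10 s; the per-seizure values are then averaged (per-seizure-
then-average, one of two defensible readings). The null displaces *all*
seizure times jointly by one uniform circular offset per shuffle (2000 by
default), preserving inter-seizure structure and seizure lengths with the
trace untouched; offsets are quantized to whole imaging frames since the
trace exists only on the frame grid. Time is treated circularly, so bins
near the recording edges wrap. Each bin's observed per-seizure sample is
compared against the pooled null sample with a two-sample KS test at
p < 0.05/30 ≈ 0.0017, and an ROI participates iff ≥ 2 adjacent bins are
significant. The null is held in float32 for memory; the observed sample is
rounded identically so the point mass at "empty bin" remains one exact tie
in both samples (a float64/float32 mismatch would split that atom and
inflate the KS statistic catastrophically).

Power note: with an observed sample of only n seizures, the KS statistic is
bounded, and at 10 seizures p < 0.0017 is effectively unreachable — by
design the test is conservative on seizure-poor recordings (< 3 seizures
additionally flags low power). Sessions with tens of seizures (typical for
this seizure type) give ~86% participation among strongly suppressed
neurons and 0% among unmodulated ones.

## Sliding-window re-classification

Windows of 7 min: the first starts at the recording start, each next one
starts just after the previous window's earliest seizure ends, so windows
advance one seizure at a time. Within a window, ictal and interictal frames
are concatenated, binned at 2 s, and rank-sum tested at α = 0.05 per
window; windows with fewer than two seizures are skipped. Per ROI the
fraction of windows in the predicted overall class vs the flipped class is
reported. Whether ictal-low windows are more stable than ictal-high is an
empirical outcome on real data; the pipeline reports the statistic without
asserting a direction.

## Synchrony

Traces are resampled to 200-ms bins (the effective temporal resolution of
the imaging); a bin belongs to a state only if all its frames do and none
is excluded. Each ROI's ictal bins are divided by its mean interictal
amplitude (interictal bins are left unnormalized, as stated; a config
switch can disable the normalization). Pearson coefficients are computed
per pair per state on the concatenated bins.

Correction 1 — circular-shuffle subtraction: for each pair and state, one
member is circularly rotated; the correlation at *every* rotation is
obtained exactly via FFT cross-correlation, the null offsets (2000,
excluding zero) are sampled from it, and corrected = raw − null mean (null
SD stored). The null carries the full rate and autocorrelation structure
but no temporal alignment, so a pure rate change contributes nothing: over
100 independent simulated pairs with five-fold state rate differences the
mean corrected coefficient is within ±0.02 of zero in both states, while a
common input planted only interictally is recovered interictally
(event-level planted correlation = shared-fraction², preserved through the
shared exponential kernel) and reads ~0 ictally.

Correction 2 — event-removal rate matching: events are maximal runs of
consecutive nonzero denoised samples, assigned to the state holding the
majority of their frames. Events from the initially more active state are
deleted in random order — skipping deletions that would move the state
means apart — until |mean ictal − mean interictal| < 0.1 ΔF/F percentage
points (absolute percentage points, one of two readings of the printed
tolerance); unreachable cells keep their best attempt and are flagged. Both
corrections agree on the sign of the ictal−interictal difference when a
genuine synchrony change is planted.

## Deconvolution

Rate inference inverts the indicator model F(t) = (events ∗ exp(−t/τ)):
first iterative smoothing — passes of 3-point median then 3-point mean
until no local maximum with prominence below 2·σ remains or 10 passes, with
samples ≥ 5σ restored verbatim after each pass (peaks that large cannot be
noise; restoring them keeps transient amplitudes undistorted, which plain
global passes would clip by ~20%) — then the exact discrete inverse,
rate(t) ∝ x(t) − e^{−Δt/τ}·x(t−Δt), rectified at zero, after referencing
the trace to its minimum (a constant offset cannot arise from decaying
events). τ defaults to 0.6 s for GCaMP6M and 1.0 s for GCaMP6S; no
published kernel constants exist for this dataset, so these are standard
indicator-kinetics values, configurable. A noiseless exponential transient
deconvolves to a single sample at its onset, and total inferred rate is
linear in transient amplitude. Classifying the inferred rates reproduces
≥ 95% of the ΔF/F class labels on the simulator.

Spike trains are converted to rates with a centered 100-ms sliding boxcar
(window fixed; it was tuned per-neuron against paired recordings in the
original setting, data this package does not have).

## Patch-clamp analysis

APs are flagged at samples t satisfying, with window bounds in ms rounded
to the nearest sample and inclusive window means:

1. V(t + 0.25 ms) > V(t) + x
2. mean V[t−pre₁, t−pre₂] < mean V[t+p₁, t+p₂] − α·x
3. mean V[t+post₁, t+post₂] < mean V[t−pre₁, t−pre₂] + β·x

with (x, pre₁, pre₂, p₁, p₂, post₁, post₂, α, β) =
(38 mV, 1.2, 0.3, 0.25, 0.35, 2.5, 2.9, 0.5, 0.8) for whole-cell and
(1.9 mV, 0.8, 0.25, 0.15, 0.24, 1.8, 2.1, 0.55, 0.45) for cell-attached
recordings. Criterion 2 is implemented exactly as printed (the subtraction
on the peak side), with a unit test pinning the literal inequality. Flagged
runs within 1 ms collapse to their earliest sample. Note the criteria
require repolarization by ~3 ms: genuine doublets with shorter intervals
are invisible to them by construction.

Per-seizure paired firing rates use the two adjacent half-gaps as each
seizure's interictal partner (partitioning interictal time without
overlap), compared by Wilcoxon signed-rank. Peri-EEG-spike histograms
reference each AP to its *nearest* EEG spike (ties to the earlier), span
±100 ms in 20-ms bins; the coincidence fraction is the proportion of EEG
spikes with ≥ 1 AP within ±20 ms, and offset normality is assessed with the
D'Agostino–Pearson test (≥ 20 offsets required).

## The synthetic-data generator

What it emulates: pink (1/f) EEG background with planted biphasic 5–15 ms
spikes at the configured 5–9 Hz riding on a sub-threshold slow wave, spike
amplitude 4× the background envelope; inhomogeneous-Poisson calcium event
trains (default 0.5 events/s interictally — the upper end of plausible
quiet-cortex rates; nothing in the source pins this down) convolved with a
single-exponential kernel, amplitude-jittered (lognormal, σ=0.3, mean 25%
ΔF/F), on a positive baseline with Gaussian noise (1% ΔF/F) and 5%
linear bleaching; per-neuron ictal classes (70/6/12/12%
low/high/neutral/quiet by default, depths −0.8/+1.5/0) whose rate
modulation engages 2 s *before* EEG onset — mirroring the observation that
population hypoactivity precedes the electrographic discharge — and ends at
offset; pairwise common input via a shared latent event train thinned into
each neuron (event-level pair correlation = fraction², optionally confined
to the interictal state); neuropil patches as means of 10 random neurons
plus reduced independent noise; locomotion bouts suppressed around
seizures; stereotyped AP waveforms sized to the detection criteria with a
4-ms refractory gap (shorter doublets cannot satisfy the repolarization
window) and none within 10 ms of the trace edges.

What it does not emulate: out-of-focus neuropil contamination of somatic
signals, motion artifacts, indicator nonlinearity/saturation, non-Poisson
firing statistics (bursts, refractoriness in the calcium trains),
electrode artifacts, or drifting noise levels. Passing recovery tests on
this generator therefore shows the *statistical machinery* is correct and
calibrated under the stated assumptions — not that those assumptions hold
in any particular recording.

Class drift (off by default) flips ictal-low/high assignments at epoch
boundaries (default 300 s) with a configurable probability, for testing the
windowed re-classification.

## Reproducibility and problem sizes

One seed drives everything; each stochastic stage derives an independent
substream keyed by a CRC of its name, so adding a stage never perturbs the
others. Re-running with identical config and seed reproduces every table
bit-for-bit; a golden-summary regression test pins a seeded 5-min fixture.
Test and acceptance runs use 5–30 min sessions with 10–200 ROIs and
500–2000 shuffles — sizes at which every calibration and recovery property
is measurable with comfortable margins while the whole suite stays fast.

## Known limitations

- The seizure detector is tuned for the planted SWD morphology; real EEG
  with artifacts or atypical discharges will need threshold adjustment or
  manual annotations (supported via CSV).
- KS-based participation is conservative below ~20 seizures (see above).
- The quiet-threshold unit convention is an interpretation; if a different
  convention is established, the thresholds are plain config values.
- The alternative published spike-inference algorithm
  (expectation-maximization) is not implemented; `deconvolve_matrix` is the
  single built-in method and external rate traces can be classified by
  wrapping them in a `DffMatrix`.
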