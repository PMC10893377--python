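# Methods

This note documents the models, defaults and numerical choices behind
`earval`, and what its synthetic-data validation does and does not
establish about real recordings.

## Recordings, markers and clocks

A `Recording` is a channels × samples matrix in microvolts on a
uniform grid at the nominal rate (typically 500 Hz). The XDF dialect
reader anchors the uniform grid at the stream's first acquisition
timestamp and assumes the nominal rate thereafter — the usual offline
regularization for regular-rate streams; per-sample timestamp drift is
not resampled. Marker streams carry their timestamps on the same
clock; any residual offset between acquisition clocks is exposed
explicitly as `MarkerStream.clock_offset` (an event stamped `t`
occurred at `t + clock_offset` on the recording clock) rather than
being resolved behind the scenes, because recorder clock-handling
conventions differ between setups.

## Trigger latency

Delivery chains delay the physical stimulus relative to the software
marker — near zero for a well-scheduled audio path, ~21 ms for a
monitor-bound visual path — with a few milliseconds of jitter. The
estimator rectifies a bench trace (photodiode or audio loopback),
searches a 0–200 ms window after each marker and takes the first
crossing of 0.5× the in-window maximum as the onset. The crossing is
linearly interpolated between the last sub-threshold and first
supra-threshold sample; for a step-like onset this makes the
quantization error symmetric (uniform on ±half a sample) instead of
biased upward by up to one sample, which is what lets the estimator
recover a 21 ms mean to well under the 2 ms sample period. Mean and
standard deviation (jitter) are reported over detected events; markers
with no crossing are counted, not silently dropped. Downstream
epoching accepts a per-modality latency correction (defaults: 0 ms
auditory, 21 ms visual) that should be re-measured per setup.

## Preprocessing

The filter chain is highpass → optional 50 Hz notch → lowpass, all
zero-phase (forward–backward): 4th-order Butterworth passes and a
second-order IIR notch (Q = 35). Zero phase is a deliberate choice —
the source pipelines for this kind of analysis rarely state their
phase handling, and causal IIR filtering would shift ERP component
latencies by several milliseconds. Forward–backward application
doubles the effective order; the stated orders are per pass. Band
defaults: 1–100 Hz for steady-state paradigms, 1–20 Hz for transients,
0.2–3 Hz to isolate blinks. The transient and blink bands omit the
notch because a 50 Hz notch under a ≤20 Hz lowpass is a no-op and the
`FilterSpec` invariant (notch inside the passband) rejects it.

Re-referencing subtracts a named channel from all channels, zeroing
the reference row and preserving all pairwise differences exactly.
Epoching rounds the corrected onset (marker + latency correction) to
the nearest sample with ties rounding up, cuts
`round((tmax−tmin)·fs)+1` samples per trial, and drops-and-counts
trials that cross the recording edges. Baseline correction subtracts
the per-trial, per-channel mean over the 100 ms pre-stimulus interval
by default.

## Spectral metrics

Welch PSD: Hann windows, 8 s, 50% overlap, one-sided density scaling;
the per-segment periodograms are retained because the peak-significance
test needs them. STFT spectrograms use 2 s windows at 50% overlap.

Narrowband SNR divides the power at the bin nearest `f0` by the mean
power of the band's other bins, excluding a one-bin mainlobe guard on
each side of `f0`. The guard matters: a bin-centered line under a Hann
taper places a quarter of its peak density in each adjacent bin, so
treating those bins as noise caps the measurable SNR (at the default
grid, near 22 dB regardless of amplitude) and breaks the expected
−6 dB change when the signal amplitude halves. With the guard, SNR is
proportional to signal power in the noise-limited regime, and the
flat-spectrum identity SNR = 1 (0 dB) is unchanged.

Peak significance is a one-way ANOVA comparing the per-segment power
at the `f0` bin against the pooled per-segment powers of the neighbor
bins. The grouping is a documented convention (the underlying
procedure is usually reported only as "an F-test on these ratios");
periodogram powers are χ²-distributed and overlapping segments are
correlated, and measured under pure noise this test runs slightly
conservative (≈0.7% rejections at α = 0.01, ≈3.3% at 0.05), which is
the safe direction for a hardware QC gate. The phantom playback check
uses α = 0.01.

Alpha blocking: `R_AM = P_closed / P_open` over 8–12 Hz, from STFT
frames whose centers fall in the condition intervals. Intervals are
derived from `eyes_closed`/`eyes_open` markers, discarding the first
2 s after each transition (settling; configurable). All ratio metrics
are reported as `10·log10` dB.

The harmonic scan evaluates the SNR at `k·f0` with a ±5 Hz neighbor
band clipped to the valid range; `find_spectral_peaks` lists local PSD
maxima above a relative height threshold (10⁻⁶ of the maximum by
default) for clean bench spectra, where a played-back square wave
shows only odd harmonics.

## ERP analyses

Trial averages carry per-timepoint one-sample two-tailed t-tests
against zero at α = 0.05, uncorrected for multiple comparisons (a
descriptive mask, as conventional for ERP plots — not an inferential
claim). Zero-variance timepoints take the limit of the t statistic:
significant when the constant mean is nonzero. Difference waves use
all deviants against only the standards that immediately precede a
deviant (balancing slow drifts), with per-timepoint Welch two-sample
t-tests — the two-sample choice is this package's convention, since
difference-wave masks are usually plotted without naming the test.
Component metrics take the signed extremum of stated polarity in a
search window (defaults: P1 30–80 ms, N1 80–150 ms, P2 150–300 ms,
MMN 100–300 ms, P300 250–500 ms; ties break to the earliest sample)
plus an optional peak-to-peak between two components.

EOG blinks are quantified as the mean within-epoch peak-to-peak after
0.2–3 Hz filtering, with the hard/soft (intentional/regular) ratio as
the headline number; no blink search is performed because epochs are
marker-locked. Saccade profiles are per-direction averages read at
200 ms post-cue, where direction separation is greatest.

## Phantom bench

Mixture calculators solve `m_i = p_i·w/(1−Σp)` for solutes at target
weight fractions `p_i` of the total mixture (reducing to the closed
forms `A = 8w/191`, `s = w/191` and `BG = 15w/77`, `s = 8w/77` at the
default percentages) and `CF = S·X/(100−X)` for the silicone
composite with `S` = volume × density (1.11 g/mL). Rounding defaults
follow bench practice: agar/salt round up to whole grams, carbon
fiber rounds to nearest; fractions above 1.0% CF warn that the
composite becomes too dense to mold. Conductivity is `σ = L/(R·A)`
with the strip geometry 30 × 10 × 2 mm as default.

Impedance QC classes partition [0, ∞) kΩ: good < 10, acceptable
10–20, poor 20–50, no-contact ≥ 50 or meter-saturated. Boundary
values take the worse class. The 10 kΩ anchor is standard EEG
practice and 50 kΩ is a typical analog meter limit; the 20 kΩ split
between acceptable and poor is this package's convention and is
configurable. Noise floor is per-channel RMS after a 0.3–100 Hz
zero-phase band-pass (wet contacts should sit near or under 1 µVrms;
open contacts read hundreds). Integrity trends report per-day deltas
and percent change from day 1 with no interpolation.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the session structure of the standard test
battery: 4 min continuous recordings (resting, alpha blocking with
four alternating 1 min blocks, 40 Hz ASSR, 10 Hz SSVEP with
harmonics), 200-trial transient blocks (AEP 200 ms tones with
1.2–1.8 s ISI; VEP 500 ms reversals with 500 ms ISI; auditory and
visual oddballs at a 0.2 deviant fraction with no consecutive
deviants, placed uniformly by the gap construction) and an 80-trial
saccade block with an appended instructed-blink section (20 hard +
20 soft at 2.5–3.5 s spacing, so the 3 s blink windows never
overlap). Sampling is 500 Hz on a 12-channel scalp + 2×8 ear montage;
markers precede physical onsets by per-modality Normal delays
(auditory 0 ± 2.2 ms, visual 21 ± 2.8 ms).

Defaults were chosen once as plausible for adult scalp EEG: pink
(1/f) background at 10 µVrms over 1–250 Hz (synthesized in the
frequency domain with known density `K/f`, so tests have an analytic
noise term), optional 50 Hz line; eyes-closed alpha 30 µV amplitude
with a closed/open power ratio of 4; ASSR 1 µV; SSVEP 2 µV with 0.5
amplitude decay per harmonic; Gaussian-sum ERP templates (AEP
P1/N1/P2 = +2/−5/+3.9 µV, giving an 8.9 µV N1–P2 span; VEP P2 +15 µV
at 200 ms; MMN −2 µV; P300 +6 µV); blinks 8000/1500 µV peak-to-peak
frontally; saccades ±5 µV horizontal and ±1 µV vertical with polarity
inversion between hemispheres and a gaze-and-return pulse shape so
consecutive trials do not accumulate. Effects are projected through
stylized per-paradigm scalp topographies (occipital alpha/SSVEP,
centro-parietal ASSR, fronto-central AEP) with ear channels at 0.3×
for cortical sources and 1.5× for horizontal eye movements; these
projection constants are emulation choices, not measurements. Phantom
recordings scale a square wave by per-electrode contact quality
(good 1.0, bad 0.02) and a position gain (0.6–1.3× by sensor number,
emulating distance from the antennas) plus white noise at the
per-class floor (0.5 / 300 µVrms).

Passing parameter-recovery tests on these data shows the analysis
chain is correct and well calibrated — it does not show robustness to
what the generator omits: non-stationary and spatially correlated
noise, eye/muscle artifacts outside the EOG block, electrode drift,
inter-subject variability, volume-conduction physics, or amplitude
nonlinearity. Grand averaging across subjects is the unweighted mean
of subject-level means (subject = one recording file).

## Problem sizes and numerical notes

The test suite validates at the full session sizes (4 min continuous
recordings, 200-trial blocks, 1000-event latency runs); null
calibrations use 220 runs of 40-trial single-channel epoch sets and
100 phantom noise recordings, sizes at which the Monte-Carlo error of
the checked rates is a few per mille. Square waves for bench spectra
are built by integer sample arithmetic when the period is a whole
number of samples: accumulating floating-point phase displaces
occasional transition samples and raises a broadband floor near
−40 dB that pollutes peak listings. Welch segment counts follow
`floor((N−L)/(L/2))+1`; sample-index rounding is nearest-with-ties-up
throughout; degenerate ANOVA groups (no within-group variance) return
F = 0, p = 1 when means agree and F = ∞, p = 0 otherwise.

## Known limitations

* The XDF reader supports the single-EEG-stream dialect (plus one
  marker stream) and does not stitch multi-file sessions or resolve
  recorder clock-offset chunks.
* Significance masks are uncorrected by design; no cluster-based or
  permutation correction is provided.
* No artifact rejection or ICA: the pipelines assume the cooperative,
  low-artifact recordings the validation protocol produces.
* The phantom model treats contact quality as binary and noise as
  white; real contact degradation is graded and colored.
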