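# Methods

`pdspeech` implements a continuous-speech assessment pipeline for
hypokinetic (Parkinsonian) dysarthria: speech enhancement, voice-activity
detection, an acoustic feature battery, spectrogram rendering, and a
CNN classification harness. Because the clinical recordings this kind of
study runs on are typically private, the package ships a first-class
synthetic-voice generator with known ground truth; every downstream claim
the test suite makes is checked against that ground truth.

## Synthetic dysarthric voices

The generator uses source–filter synthesis. The voiced source is a glottal
impulse train at the profile's pitch, with three perturbations:

* cycle-to-cycle **jitter** (fractional period perturbation, default 1%),
* a slow **intonation drift** (a smoothed random walk scaled to `f0_sd`,
  giving the intended pitch variability σ(f0)),
* a weak **aspiration-noise floor** (default 1% of pulse amplitude).

The impulse source matters: it has a flat spectrum, so after the cascade of
three second-order all-pole resonators (the vocal-tract model) the voiced
signal is genuinely all-pole and the resonator frequencies are recoverable
by LPC — the property the formant stage is validated against. A
glottal-pulse-shaped source (e.g. Rosenberg) adds ≈ −12 dB/oct of tilt that
buries the second and third formants tens of dB below the first, which
makes a ±10% formant-recovery check unattainable at any LPC configuration
we tried; we therefore model the glottal shaping as *not* part of the
source and accept the buzzier timbre (perceptual realism is a non-goal).

Each uttering is amplitude-modulated (mono-loudness knob `loudness_sd`, a
fractional depth with excursion clipped at ±2 sd) and peak-normalized to
`loudness`. Utterings alternate with true silences; durations are drawn
per segment from the profile's (mean, sd) and **quantized to the 20 ms
analysis frame grid**, so the ground-truth segmentation is exactly
representable by a frame-based detector. Edge pauses are added at both
ends. Additive white Gaussian ambient noise is calibrated so that the
speech/silence power-ratio SNR *measured on the ground-truth segmentation*
equals `noise_snr_db` (default 30 dB, a quiet-room level).

Default class profiles encode the canonical hypokinetic contrasts:

| knob | HC-like | PD-like | measured effect |
| --- | --- | --- | --- |
| utterings × duration | 9 × 1.4 s | 13 × 0.9 s | higher n_uttering, r_speech |
| pause duration | 0.50 s | 0.65 s | higher n_pause, t_pause |
| loudness (peak) | 0.5 | 0.158 (−10 dB) | lower µ(I), µ(mav), µ(rms) |
| loudness_sd | 0.12 | 0.06 | lower σ(I) (mono-loudness) |
| f0 mean / sd | 170 / 25 Hz | 155 / 12 Hz | lower µ(f0), σ(f0) (mono-pitch) |
| formant bandwidths | 80/120/200 Hz | 120/300/500 Hz | lower µ(ZC), µ(maxf) (damped upper formants) |

`loudness_sd` defaults are modest by design: deeper modulation drives
within-uttering frame energy below the 1/10-of-maximum VAD threshold, and
exact uttering recovery under default conditions is part of the generator's
contract. What the generator does **not** emulate: consonants and phonetic
content, breath noise structure, room reverberation, non-stationary clinic
noise (background talk), microphone coloration. Passing tests therefore
demonstrate that the pipeline measures what it claims on controlled
all-pole voices — not that the classifier's synthetic accuracy transfers
to clinical recordings.

## Wiener enhancement

The denoiser is the classical frequency-domain Wiener gain
W(f) = ζ(f)/(ζ(f)+1), applied per STFT bin (20 ms Hann window, 50%
overlap, perfect-reconstruction overlap-add). ζ is estimated as
max(P̂_yy/P̂_nn − 1, 0): negative values are estimator artifacts and are
clamped. P̂_yy is exponentially smoothed across frames (factor 0.6 — enough
variance reduction to avoid musical noise without smearing onsets); the
gain is clamped to [0.05, 1], the floor preventing hard spectral zeros.
P̂_nn is the mean periodogram over STFT frames whose *entire window* lies
inside VAD-detected silence (boundary windows would leak speech power);
if no such frame exists the leading 10 frames are used.

Metrics: global SNR = 10·log10 of mean speech-segment power over mean
silence-segment power (+∞ sentinel for zero noise); SNRI defined as
SNR(filtered) − SNR(original) so that enhancement is positive; MSE as the
mean squared sample difference. At very low input SNR (≈5 dB) the energy
VAD finds no silence at all — the noise floor exceeds 1/10 of the maximum
energy — so enhancement measurements use the ground-truth segmentation
(`vad_from_segments`); the detector-based path is exercised at the default
30 dB condition.

## VAD and features

VAD: 20 ms non-overlapping rectangular frames, mean-square energy per
frame, speech iff energy **strictly** exceeds max(energy)/10 (an all-zero
signal is thus all-pause). Runs of equal labels become half-open
sample-interval segments; leading/trailing pauses are trimmed before
assessment. Phonology counts (n_uttering, n_pause = interior pauses,
speech rate per minute, total pause time) are computed on the trimmed span;
the speech-rate denominator is the trimmed span (config-switchable).

Feature battery on extracted utterings (20 ms rectangular frames, 50%
overlap, trailing partial dropped):

* **Intensity** I = 20·log10(rms/I_ref) with I_ref = 1e−4 full scale — an
  arbitrary-dB scale; only relative contrasts are meaningful.
* **Pitch**: short-time autocorrelation (40 ms frames, 20 ms hop), search
  range 75–400 Hz, voicing by normalized-autocorrelation peak > 0.5,
  parabolic peak interpolation. Unvoiced frames are omitted.
* **Time domain**: mav, enrg, rms and the ZC / slope-sign-change counts
  (strict sign products).
* **Frequency domain**: per-frame periodogram; maxf (argmax frequency),
  waf (P²-weighted mean frequency), and skewness/kurtosis (Pearson,
  non-excess) of the periodogram value distribution.
* **Formants**: signal downsampled to 16 kHz (polyphase FIR), 2 ms frames
  with 50% overlap, **Burg-method** LPC of order 12. The classical
  autocorrelation method is hopelessly biased on 32-sample frames (no
  frame survives the bandwidth filter); Burg's lattice recursion needs no
  windowing and keeps the poles usable. Formant candidates are root angles
  with bandwidth −(rate/π)·ln|r| < 400 Hz; the three lowest are reported,
  frames with fewer than three candidates are dropped.

Per-subject summaries pool frames across all utterings before taking the
mean and sample (n−1) standard deviation; an f0 track with no voiced
frames is recorded as missing, a single value gets sd 0 with a warning.

## Spectrograms and classification

Three views per uttering, all 20 ms / 50% rectangular frames, power in dB
floored at −80 dB: log-power STFT ("speech"), an energy-normalized view in
which each frame's bins sum linearly to the frame's mean-square energy
("energy"), and a 64-band HTK-mel filterbank view ("mel"). Rendering is
pinned for reproducibility: absolute dB scale mapped onto [−80, 0] dB re
full scale (so loudness differences stay visible across images), viridis
colormap, square bilinear resize to 224 px, JPEG quality 95 — identical
input yields byte-identical files.

The classifier is a from-scratch depthwise-separable CNN (stem 3×3 stride-2
convolution, thirteen depthwise+pointwise blocks including the five
repeated 512-channel blocks, spatial sequence 224→112→56→28→14→7, global
average pool). Every convolution is followed by batch normalization and
ReLU. The head is a 2-unit softmax trained with cross-entropy — the binary
form of the published recipe, replacing the 1000-way ImageNet head, whose
final listed stride would also contradict the 7×7 pool and is taken as
stride 1. The layers are implemented directly in numpy (im2col
convolutions with hand-derived gradients, verified against finite
differences in the test suite); no deep-learning framework is required.
Training: SGD with momentum 0.9 at learning rate 0.005, optional
augmentation (random contrast ±0.3, horizontal flip, rotation ±0.18 of a
turn), fully seeded. Splits are stratified 80/20 with 20% of the training
portion held out for validation; an optional subject-grouped mode prevents
a subject's utterings from spanning partitions (recommended — image-level
splitting leaks speaker identity).

Desk-scale runs (tests, acceptance script) use width multiplier 0.25,
64 px inputs, 30 epochs and batch 32: with ~135 training images the
full-scale batch of 128 would give a single gradient update per epoch.
Full-scale defaults (width 1.0, 224 px, batch 128, 100 epochs) remain the
config defaults.

## Subject exclusion ("dataset reduction")

A subject is excluded when any configured phonological feature falls
outside its class's mean ± k·sd interval (k = 1 by default), computed from
the cohort's own feature table; all of the subject's images leave the
image manifest and the per-subject decisions are returned as a table. An
`opposite`-class comparison mode is provided. Note the statistical quirk
this rule inherits: with small cohorts the interval is computed *including*
outliers, so a gross outlier inflates the interval it is judged against —
it is still excluded, but borderline subjects may not be.

## Numerical conventions and edge cases

* PCM scaling is symmetric (sample/2^(bits−1)); multi-channel input is
  averaged to mono; out-of-range samples are clipped with a warning on
  write (or rejected per flag).
* All-zero frames: excluded from spectral features (undefined maxf/waf),
  intensity mapped to a −40 dB floor, LPC frames dropped.
* Problem sizes in the shipped tests and acceptance script — ~18 s
  cohort samples, 10+10 subjects for the contrast study, 8+12 subjects
  (≥100 images/class) for classification, 10 noise seeds per SNR level —
  were chosen so the whole suite runs in minutes on one CPU core while
  keeping every statistic comfortably clear of its decision boundary.

## Known limitations

* The synthetic cohort is linearly separable by design (loudness and pause
  structure); near-perfect scaled-down classification accuracy is a
  pipeline-correctness check, not a clinical performance estimate.
* Feature standard deviations on continuous speech mix trait variability
  with phonetic variability; sustained-phonation analysis (jitter,
  shimmer, HNR) is out of scope.
* The Wiener stage assumes stationary, uncorrelated noise; babble or
  impulsive clinic noise violates this and is partly treated as speech.
* The energy VAD fails below ≈10 dB SNR (threshold is relative to maximum
  energy); no hangover smoothing is applied by default.
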