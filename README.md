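# pdspeech

Continuous-speech assessment for hypokinetic (Parkinsonian) dysarthria.

Speech impairment is one of the earliest presentations of Parkinson's
disease (PD): reduced loudness, mono-pitch and mono-loudness oration,
inappropriate pauses, imprecise articulation. `pdspeech` implements a full
digital-biomarker pipeline for continuous (read) speech recorded in noisy
rooms, for researchers who want a tested, reproducible reference of the
classical assessment chain:

1. **Wiener denoising** — frequency-domain gain W(f) = ζ/(ζ+1) with the
   per-bin SNR ζ̂ = max(P̂_yy/P̂_nn − 1, 0), noise PSD from VAD-silence
   frames; evaluated by global SNR (speech-segment vs silence-segment
   power), SNR improvement, and MSE.
2. **Voice-activity detection** — 20 ms non-overlapping frame energies
   against a threshold of 1/10 of the maximum frame energy; utterings and
   pauses, with edge-pause trimming.
3. **Feature battery** — phonology (n_uttering, n_pause, r_speech,
   t_pause), prosody (I, f0), time domain (mav, enrg, rms, ZC, SSC),
   frequency domain (maxf, waf, spectral skewness/kurtosis), and LPC
   formants (f1–f3 at 16 kHz, 2 ms frames), summarized per subject as
   µ and σ.
4. **Spectrogram classification** — speech / energy / Mel spectrograms per
   uttering exported as 224×224 JPEGs and classified PD-vs-HC by a
   MobileNet-style depthwise-separable CNN (implemented in pure numpy,
   trained with SGD at lr 0.005, accuracy = (TP+TN)/(TP+TN+FP+FN)).
5. **Synthetic cohorts** — a source–filter voice generator with exact
   ground truth (segment boundaries, pitch tracks, clean signal) and
   PD-like/HC-like trait profiles, standing in for private clinical
   recordings so the whole chain is verifiable end to end.

Everything is seeded and deterministic; the same assessment runs on the
original and the Wiener-filtered signal ("dual condition") so filtering
effects can be quantified.

## Worked example

```sh
pdspeech synth-cohort --n-pd 2 --n-hc 2 --out demo/cohort --seed 1
pdspeech assess --manifest demo/cohort/manifest.csv --out demo/results
pdspeech report --out demo/results
```

This synthesizes four ~18 s "subjects", assesses them in both conditions
and prints per-class means. Abridged output of the report step:

```
== enhancement.csv (4 rows) ==
       snr_orig_db  snr_filt_db  snri_db  mse
label
HC          29.990       39.150    9.160  0.0
PD          30.003       39.395    9.392  0.0
== features.csv (8 rows) ==  (columns abridged)
       n_uttering  n_pause  t_pause_s    mu_I    mu_f0   sd_f0  mu_mav   mu_ZC
label
HC            9.0      8.0       3.83  60.961  168.965  21.460   0.081  29.266
PD           13.0     12.0       8.30  51.485  154.742   9.498   0.026  24.241
```

Read: Wiener filtering raised the measured SNR by ~9 dB on both classes
(from the 30 dB synthesis condition), with an MSE below the printed
precision; the PD-like subjects show more and longer pauses (n_pause 12
vs 8, t_pause 8.3 s vs 3.8 s), ~10 dB lower intensity (µ(I)), lower pitch
with less than half the variability (σ(f0) 9.5 vs 21.5 Hz) and weaker
amplitude and zero-crossing features — the hypokinetic pattern the
feature battery is designed to expose. A CNN over
the exported spectrogram images is then trained per spectrogram kind and
condition with `pdspeech train --images demo/results/image_manifest.csv
--out demo/cnn --width-multiplier 0.25 --input-size 64 --epochs 30`
(add `--subject-grouped` to prevent speaker leakage across partitions).

The library surface mirrors the CLI: `synth_speech_sample`,
`wiener_filter`, `detect_voice_activity`, `assess_signal`,
`run_assessment`, `reduce_dataset`, `run_classification`, etc. — see the
module docstrings and `docs/methods.md` for the model details and design
choices.

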