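"""Wiener filter limits, noise-PSD estimation and enhancement metrics."""

from dataclasses import replace

import numpy as np
import pytest

from pdspeech.audio_io import AudioSignal
from pdspeech.synthvoice import synth_speech_sample
from pdspeech.vad import detect_voice_activity, frame_energy, vad_from_segments
from pdspeech.wiener import (
    WienerConfig,
    estimate_noise_psd,
    mse,
    snr_db,
    snr_improvement,
    wiener_filter,
)

RATE = 16000


def test_noise_psd_white_noise_level(rng):
    """Mean periodogram of white noise matches the analytic per-bin power."""
    sigma = 0.1
    x = AudioSignal(rng.normal(0, sigma, RATE * 4), RATE)
    config = WienerConfig(noise_est="leading_frames", noise_frames=10**6)
    psd = estimate_noise_psd(x, config)
    # hann-window STFT: E|X(k)|^2 = sigma^2 * sum(w^2) for interior bins
    nperseg = int(RATE * 0.02)
    from scipy.signal.windows import hann

    expected = sigma**2 * np.sum(hann(nperseg, sym=False) ** 2)
    interior = psd[2:-2]
    assert abs(np.mean(interior) - expected) / expected < 0.1


def test_noise_psd_zero_signal():
    x = AudioSignal(np.zeros(RATE), RATE)
    psd = estimate_noise_psd(x, WienerConfig(noise_est="leading_frames"))
    assert np.all(psd == 0)


def test_noise_psd_vad_silence_uses_silence_only(rng):
    """With a tone+silence signal the estimate reflects the silence floor."""
    n = RATE * 2
    x = np.zeros(n)
    t = np.arange(n // 2) / RATE
    x[: n // 2] = 0.5 * np.sin(2 * np.pi * 440 * t)  # tone half
    x[n // 2 :] = rng.normal(0, 1e-3, n - n // 2)  # near-silent half
    sig = AudioSignal(x, RATE)
    psd = estimate_noise_psd(sig, WienerConfig(noise_est="vad_silence"))
    freqs = np.fft.rfftfreq(int(RATE * 0.02), 1 / RATE)
    tone_bin = np.argmin(np.abs(freqs - 440))
    # tone power would dominate by orders of magnitude if speech frames leaked in
    assert psd[tone_bin] < 1e-3


def test_identity_limit_zero_noise_estimate(rng):
    """Zero noise spectrum -> unit gain -> output equals input."""
    x = AudioSignal(rng.normal(0, 0.1, RATE), RATE)
    config = WienerConfig(psd_smoothing=0.0)
    out, gain = wiener_filter(x, config, noise_psd=np.zeros(161))
    assert np.all(gain == 1.0)
    np.testing.assert_allclose(out.samples, x.samples, atol=1e-7)


def test_pure_noise_attenuated_to_floor(rng):
    """Noise matching the estimate is pushed down toward the gain floor."""
    sigma = 0.05
    x = AudioSignal(rng.normal(0, sigma, RATE * 2), RATE)
    config = WienerConfig(noise_est="leading_frames", noise_frames=10**6)
    out, gain = wiener_filter(x, config)
    in_power = np.mean(x.samples**2)
    out_power = np.mean(out.samples**2)
    # most bins sit exactly at the floor; residual power reflects the
    # variance of the per-frame spectrum estimate around the true noise PSD
    assert np.median(gain) == config.gain_floor
    assert out_power <= 0.15 * in_power
    assert gain.min() >= config.gain_floor
    assert gain.max() <= 1.0


def test_gain_bounds_on_speech(small_hc):
    sig, _ = synth_speech_sample(small_hc)
    _, gain = wiener_filter(sig)
    assert gain.min() >= WienerConfig().gain_floor
    assert gain.max() <= 1.0


def test_output_length_preserved(small_hc):
    sig, _ = synth_speech_sample(small_hc)
    out, _ = wiener_filter(sig)
    assert len(out) == len(sig)


def test_snr_closed_forms():
    # speech power 100x silence power -> 20 dB
    x = np.concatenate([np.full(3200, 1.0), np.full(3200, 0.1)])
    vad = vad_from_segments([(0.0, 0.2, "speech"), (0.2, 0.4, "pause")], RATE)
    assert snr_db(AudioSignal(x, RATE), vad) == pytest.approx(20.0, abs=1e-9)
    y = np.concatenate([np.full(3200, 0.5), np.full(3200, 0.5)])
    assert snr_db(AudioSignal(y, RATE), vad) == pytest.approx(0.0, abs=1e-9)
    # zero noise -> +inf sentinel
    z = np.concatenate([np.full(3200, 0.5), np.zeros(3200)])
    assert snr_db(AudioSignal(z, RATE), vad) == np.inf


def test_snr_requires_both_segment_kinds():
    vad = vad_from_segments([(0.0, 0.4, "speech")], RATE)
    with pytest.raises(ValueError):
        snr_db(AudioSignal(np.ones(6400), RATE), vad)


def test_snr_improvement_closed_forms():
    vad = vad_from_segments([(0.0, 0.2, "speech"), (0.2, 0.4, "pause")], RATE)
    x = np.concatenate([np.full(3200, 1.0), np.full(3200, 0.1)])
    sig = AudioSignal(x, RATE)
    assert snr_improvement(sig, sig, vad, vad) == pytest.approx(0.0)
    # 10x less silence-segment noise power, same speech power -> +10 dB
    y = np.concatenate([np.full(3200, 1.0), np.full(3200, 0.1 / np.sqrt(10))])
    assert snr_improvement(sig, AudioSignal(y, RATE), vad, vad) == pytest.approx(10.0, abs=1e-9)


def test_mse_closed_forms_and_oracle(rng):
    a = AudioSignal(rng.normal(0, 0.3, 2000), RATE)
    assert mse(a, a) == 0.0
    shifted = AudioSignal(a.samples + 0.01, RATE)
    assert mse(a, shifted) == pytest.approx(1e-4, rel=1e-9)
    b = AudioSignal(rng.normal(0, 0.3, 2000), RATE)
    brute = sum((x - y) ** 2 for x, y in zip(a.samples, b.samples)) / 2000
    assert mse(a, b) == pytest.approx(brute, abs=1e-12)
    with pytest.raises(ValueError):
        mse(a, AudioSignal(np.zeros(10), RATE))


def test_end_to_end_enhancement(small_hc):
    """Filtering noisy synthetic speech raises SNR and lowers clean-signal MSE."""
    prof = replace(small_hc, noise_snr_db=10.0, seed=3)
    sig, truth = synth_speech_sample(prof)
    filt, _ = wiener_filter(sig)
    vad = vad_from_segments(truth.segments, sig.rate)
    assert snr_improvement(sig, filt, vad, vad) > 0
    assert mse(truth.clean, filt) < mse(truth.clean, sig)


def test_config_validation():
    with pytest.raises(ValueError):
        WienerConfig(gain_floor=1.5)
    with pytest.raises(ValueError):
        WienerConfig(overlap=1.0)
    with pytest.raises(ValueError):
        WienerConfig(noise_est="bogus")
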