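"""Feature battery: framing, closed forms, oracles, parameter recovery."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.signal import lfilter

from pdspeech.audio_io import AudioSignal, resample
from pdspeech.features import (
    FrameSpec,
    frame_segment,
    intensity_track,
    lpc_formants,
    pitch_track,
    spectral_features,
    summarize_features,
    time_features,
)
from pdspeech.features import FeatureTrack
from pdspeech.synthvoice import _resonator_coeffs, synth_uttering

RATE = 44100


def test_frame_counting():
    # 100 ms at 44.1 kHz, 20 ms / 50% -> 9 frames
    seg = AudioSignal(np.zeros(4410), RATE)
    assert frame_segment(seg).shape == (9, 882)
    # exactly one frame
    assert frame_segment(AudioSignal(np.zeros(882), RATE)).shape == (1, 882)
    with pytest.raises(ValueError):
        frame_segment(AudioSignal(np.zeros(100), RATE))


def test_frame_contents_match_slicing(rng):
    x = rng.normal(0, 0.2, 5000)
    frames = frame_segment(AudioSignal(x, RATE), FrameSpec(20.0, 0.5))
    hop = 441
    for k in range(frames.shape[0]):
        np.testing.assert_array_equal(frames[k], x[k * hop : k * hop + 882])


def test_intensity_closed_forms():
    ref = 1e-4
    frames = np.full((1, 100), ref)
    assert intensity_track(frames, ref=ref).values[0] == pytest.approx(0.0, abs=1e-9)
    frames10 = np.full((1, 100), 10 * ref)
    assert intensity_track(frames10, ref=ref).values[0] == pytest.approx(20.0, abs=1e-9)
    silent = np.zeros((1, 100))
    assert intensity_track(silent, ref=ref, floor_db=-40.0).values[0] == -40.0


def test_intensity_halving_drops_six_db(rng):
    frames = rng.normal(0, 0.1, (20, 882))
    full = intensity_track(frames).values.mean()
    half = intensity_track(frames / 2).values.mean()
    assert half - full == pytest.approx(-20 * np.log10(2), abs=1e-9)


def test_time_features_hand_values():
    tracks = time_features(np.array([[1.0, -1.0, 1.0, -1.0]]))
    assert tracks["ZC"].values[0] == 3
    tracks2 = time_features(np.array([[0.0, 1.0, 0.0, 1.0]]))
    assert tracks2["SSC"].values[0] == 2
    const = time_features(np.full((1, 8), -0.5))
    assert const["mav"].values[0] == pytest.approx(0.5)
    assert const["enrg"].values[0] == pytest.approx(0.25)
    assert const["rms"].values[0] == pytest.approx(0.5)
    assert const["ZC"].values[0] == 0
    assert const["SSC"].values[0] == 0


def test_scale_behavior(rng):
    """mav/rms linear, enrg quadratic; ZC/SSC/maxf/waf/skw/kur amplitude-invariant."""
    frames = rng.normal(0, 0.1, (10, 441))
    a = 0.37
    t1, t2 = time_features(frames), time_features(a * frames)
    np.testing.assert_allclose(t2["mav"].values, a * t1["mav"].values, rtol=1e-9)
    np.testing.assert_allclose(t2["rms"].values, a * t1["rms"].values, rtol=1e-9)
    np.testing.assert_allclose(t2["enrg"].values, a**2 * t1["enrg"].values, rtol=1e-9)
    np.testing.assert_array_equal(t2["ZC"].values, t1["ZC"].values)
    np.testing.assert_array_equal(t2["SSC"].values, t1["SSC"].values)
    s1, s2 = spectral_features(frames, RATE), spectral_features(a * frames, RATE)
    np.testing.assert_allclose(s2["maxf"].values, s1["maxf"].values)
    np.testing.assert_allclose(s2["waf"].values, s1["waf"].values, rtol=1e-9)
    np.testing.assert_allclose(s2["skw"].values, s1["skw"].values, rtol=1e-7)
    np.testing.assert_allclose(s2["kur"].values, s1["kur"].values, rtol=1e-7)


def test_spectral_single_line():
    n = 882
    k = 6  # exact bin
    t = np.arange(n)
    freq = k * RATE / n
    frame = np.sin(2 * np.pi * k * t / n)[None, :]
    feats = spectral_features(frame, RATE)
    bin_hz = RATE / n
    assert abs(feats["maxf"].values[0] - freq) <= bin_hz
    assert abs(feats["waf"].values[0] - freq) <= bin_hz


def test_spectral_two_equal_lines_average():
    n = 882
    t = np.arange(n)
    k1, k2 = 4, 8
    frame = (np.sin(2 * np.pi * k1 * t / n) + np.sin(2 * np.pi * k2 * t / n))[None, :]
    feats = spectral_features(frame, RATE)
    mid = (k1 + k2) / 2 * RATE / n
    assert abs(feats["waf"].values[0] - mid) <= RATE / n


def test_pitch_sine_and_pulse_train():
    t = np.arange(RATE) / RATE
    sine = AudioSignal(0.5 * np.sin(2 * np.pi * 200 * t), RATE)
    assert np.median(pitch_track(sine).values) == pytest.approx(200.0, abs=2.0)


def test_pitch_on_synthetic_voice(steady_voice, rng):
    prof = replace(steady_voice, f0_mean=150.0)
    sig, _ = synth_uttering(prof, 1.0, rng)
    track = pitch_track(sig)
    assert np.median(track.values) == pytest.approx(150.0, abs=2.0)


def test_white_noise_mostly_unvoiced(rng):
    noise = AudioSignal(rng.normal(0, 0.1, RATE), RATE)
    track = pitch_track(noise)
    n_frames = (RATE - int(0.04 * RATE)) // int(0.02 * RATE) + 1
    assert track.values.size <= 0.1 * n_frames


def test_lpc_formant_recovery(steady_voice, rng):
    sig, _ = synth_uttering(steady_voice, 1.0, rng)
    formants = lpc_formants(resample(sig, 16000))
    med = np.median(formants, axis=0)
    for target, got in zip((500.0, 1500.0, 2500.0), med):
        assert abs(got - target) / target <= 0.10
    assert np.all(formants[:, 0] < formants[:, 1])
    assert np.all(formants[:, 1] < formants[:, 2])


def test_lpc_single_resonator_white_noise(rng):
    b, a = _resonator_coeffs(800.0, 100.0, 16000)
    x = lfilter(b, a, rng.standard_normal(16000))
    formants = lpc_formants(AudioSignal(x / np.max(np.abs(x)), 16000))
    # the lowest narrow-band candidate tracks the single resonance
    assert np.median(formants[:, 0]) == pytest.approx(800.0, abs=80.0)


def test_lpc_rejects_wrong_rate_and_order(steady_voice, rng):
    sig, _ = synth_uttering(steady_voice, 0.3, rng)
    with pytest.raises(ValueError):
        lpc_formants(sig)  # still 44.1 kHz
    with pytest.raises(ValueError):
        lpc_formants(resample(sig, 16000), order=40)


def test_summarize_features_conventions():
    tracks = {"x": [FeatureTrack("x", np.array([1.0, 2.0, 3.0]))]}
    summary = summarize_features(tracks)
    assert summary.stats["x"] == (pytest.approx(2.0), pytest.approx(1.0))
    with pytest.warns(UserWarning, match="single value"):
        single = summarize_features({"y": [FeatureTrack("y", np.array([5.0]))]})
    assert single.stats["y"] == (5.0, 0.0)
    empty = summarize_features({"f0": []})
    assert np.isnan(empty.stats["f0"][0])
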