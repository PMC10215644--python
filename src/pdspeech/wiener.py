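"""Frequency-domain Wiener noise suppression and enhancement metrics.

The filter applies the classical spectral gain W(f) = zeta(f) / (zeta(f) + 1)
per STFT bin, where zeta is the a-posteriori-derived SNR estimate
max(P_yy / P_nn - 1, 0). The noise power spectrum P_nn is taken from frames
an energy VAD labels silent (falling back to the leading frames when no
silence is available), matching the convention of the global SNR metric,
which also uses silence segments as the noise reference.

Metrics: global SNR (speech-segment power over silence-segment power, dB),
SNR improvement (filtered minus original, so that enhancement is positive),
and mean squared sample error between two waveforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import ShortTimeFFT
from scipy.signal.windows import hann

from .audio_io import AudioSignal
from .vad import VadResult, detect_voice_activity, frame_energy

__all__ = [
    "WienerConfig",
    "EnhancementMetrics",
    "estimate_noise_psd",
    "wiener_filter",
    "snr_db",
    "snr_improvement",
    "mse",
]


@dataclass(frozen=True)
class WienerConfig:
    """STFT and estimator settings for the Wiener stage."""

    frame_len_ms: float = 20.0
    overlap: float = 0.5
    window_shape: str = "hann"
    noise_est: str = "vad_silence"  # or "leading_frames"
    noise_frames: int = 10  # used by the leading_frames fallback
    gain_floor: float = 0.05
    psd_smoothing: float = 0.6  # exponential smoothing of P_yy across frames

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError("overlap must lie in [0, 1)")
        if not 0.0 <= self.gain_floor < 1.0:
            raise ValueError("gain_floor must lie in [0, 1)")
        if not 0.0 <= self.psd_smoothing < 1.0:
            raise ValueError("psd_smoothing must lie in [0, 1)")
        if self.noise_est not in ("vad_silence", "leading_frames"):
            raise ValueError(f"unknown noise_est mode {self.noise_est!r}")


@dataclass(frozen=True)
class EnhancementMetrics:
    """Per-run speech-enhancement and fidelity measures (dB, dB, dB, amp^2)."""

    snr_original_db: float
    snr_filtered_db: float
    snri_db: float
    mse: float

    def as_dict(self) -> dict[str, float]:
        return {
            "snr_orig_db": self.snr_original_db,
            "snr_filt_db": self.snr_filtered_db,
            "snri_db": self.snri_db,
            "mse": self.mse,
        }


def _make_stft(config: WienerConfig, rate: int) -> ShortTimeFFT:
    nperseg = int(round(rate * config.frame_len_ms / 1000.0))
    hop = max(int(round(nperseg * (1.0 - config.overlap))), 1)
    if config.window_shape == "hann":
        win = hann(nperseg, sym=False)
    elif config.window_shape == "rectangular":
        win = np.ones(nperseg)
    else:
        raise ValueError(f"unsupported window {config.window_shape!r}")
    return ShortTimeFFT(win, hop=hop, fs=rate, fft_mode="onesided")


def estimate_noise_psd(
    signal: AudioSignal, config: WienerConfig, vad: VadResult | None = None
) -> np.ndarray:
    """Noise power spectrum per STFT bin (|Y|^2 averaged over noise frames).

    In ``vad_silence`` mode the average runs over STFT frames centred inside
    VAD pause segments (a first VAD pass is run when ``vad`` is not given);
    ``leading_frames`` uses the first ``noise_frames`` STFT frames.
    """
    stft = _make_stft(config, signal.rate)
    spec = stft.stft(signal.samples)
    power = np.abs(spec) ** 2
    n_frames = power.shape[1]
    if n_frames < 1:
        raise ValueError("signal too short for one STFT frame")

    if config.noise_est == "vad_silence":
        if vad is None:
            vad = detect_voice_activity(frame_energy(signal))
        centers = stft.hop * np.arange(n_frames)  # sample index of frame centre
        half = stft.win.size // 2
        mask = np.zeros(n_frames, dtype=bool)
        for a, b in vad.pause_segments():
            # only frames whose whole window lies in silence: boundary frames
            # would leak speech power into the noise estimate
            mask |= (centers - half >= a) & (centers + half <= b)
        if not np.any(mask):
            raise ValueError("no silent frames available for noise estimation")
        return power[:, mask].mean(axis=1)
    k = min(config.noise_frames, n_frames)
    return power[:, :k].mean(axis=1)


def wiener_filter(
    signal: AudioSignal,
    config: WienerConfig = WienerConfig(),
    noise_psd: np.ndarray | None = None,
) -> tuple[AudioSignal, np.ndarray]:
    """Apply the spectral Wiener gain; returns (filtered signal, gain matrix).

    Per bin and frame: zeta = max(P_yy / P_nn - 1, 0), gain = zeta/(zeta+1)
    clamped to [gain_floor, 1]; P_yy is the exponentially smoothed squared
    magnitude. Reconstruction uses perfect-reconstruction overlap-add; the
    output has the input's length.
    """
    stft = _make_stft(config, signal.rate)
    spec = stft.stft(signal.samples)
    if noise_psd is None:
        try:
            noise_psd = estimate_noise_psd(signal, config)
        except ValueError:
            fallback = WienerConfig(
                frame_len_ms=config.frame_len_ms,
                overlap=config.overlap,
                window_shape=config.window_shape,
                noise_est="leading_frames",
                noise_frames=config.noise_frames,
                gain_floor=config.gain_floor,
                psd_smoothing=config.psd_smoothing,
            )
            noise_psd = estimate_noise_psd(signal, fallback)

    power = np.abs(spec) ** 2
    if config.psd_smoothing > 0:
        a = config.psd_smoothing
        smoothed = np.empty_like(power)
        smoothed[:, 0] = power[:, 0]
        for k in range(1, power.shape[1]):
            smoothed[:, k] = a * smoothed[:, k - 1] + (1.0 - a) * power[:, k]
        power = smoothed

    with np.errstate(divide="ignore", invalid="ignore"):
        zeta = power / noise_psd[:, None] - 1.0
    zeta = np.where(np.isfinite(zeta), zeta, np.inf)  # zero noise -> identity
    zeta = np.maximum(zeta, 0.0)
    with np.errstate(invalid="ignore"):
        gain = np.where(np.isinf(zeta), 1.0, zeta / (zeta + 1.0))
    gain = np.clip(gain, config.gain_floor, 1.0)

    out = stft.istft(spec * gain, k1=signal.samples.size)
    out = np.real(out[: signal.samples.size])
    if out.size < signal.samples.size:
        out = np.pad(out, (0, signal.samples.size - out.size))
    return AudioSignal(out, signal.rate), gain


def snr_db(signal: AudioSignal, vad: VadResult) -> float:
    """Global SNR: 10*log10 of speech-segment power over silence-segment power.

    Returns ``inf`` when the silence segments carry zero power.
    """
    speech = vad.speech_segments()
    silence = vad.pause_segments()
    if not speech or not silence:
        raise ValueError("need at least one speech and one silence segment")
    x = signal.samples
    p_signal = np.concatenate([x[a:b] for a, b in speech])
    p_noise = np.concatenate([x[a:b] for a, b in silence])
    ps = float(np.mean(p_signal**2))
    pn = float(np.mean(p_noise**2))
    if pn == 0.0:
        return float("inf")
    return 10.0 * np.log10(ps / pn)


def snr_improvement(
    original: AudioSignal,
    filtered: AudioSignal,
    vad_orig: VadResult,
    vad_filt: VadResult,
) -> float:
    """SNR(filtered) - SNR(original) in dB: positive means enhancement."""
    return snr_db(filtered, vad_filt) - snr_db(original, vad_orig)


def mse(original: AudioSignal, filtered: AudioSignal) -> float:
    """Mean squared sample difference between two equal-length signals."""
    if len(original) != len(filtered):
        raise ValueError(
            f"length mismatch: {len(original)} vs {len(filtered)} samples"
        )
    return float(np.mean((original.samples - filtered.samples) ** 2))
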