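"""Spectrogram generation and fixed-size image export for classification.

Three views of a speech segment are produced, all in dB with a hard floor:

* speech spectrogram — log-magnitude STFT (power dB);
* energy spectrogram — per-frame power spectrum renormalized so its bins
  sum (linearly) to the frame's mean-square energy, i.e. a view of how each
  frame's energy distributes over frequency;
* Mel spectrogram — triangular HTK-style mel filterbank over the per-frame
  power spectra, log-compressed.

Images are rendered on an absolute dB scale (db_floor .. 0 dB re full
scale) with a fixed colormap, resized to a square RGB raster and JPEG
encoded, so identical inputs produce byte-identical files and loudness
differences remain visible across images.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from matplotlib import colormaps
from PIL import Image

from .audio_io import AudioSignal

__all__ = [
    "SpectroParams",
    "SpectrogramImage",
    "speech_spectrogram",
    "energy_spectrogram",
    "mel_spectrogram",
    "export_image",
    "hz_to_mel",
    "mel_to_hz",
]


@dataclass(frozen=True)
class SpectroParams:
    """Rendering parameters shared by the three spectrogram kinds."""

    kind: str = "speech"  # speech | energy | mel
    frame_len_ms: float = 20.0
    overlap: float = 0.5
    mel_bands: int = 64
    db_floor: float = -80.0
    image_size: int = 224
    colormap: str = "viridis"

    def __post_init__(self) -> None:
        if self.kind not in ("speech", "energy", "mel"):
            raise ValueError(f"unknown spectrogram kind {self.kind!r}")
        if self.image_size <= 0:
            raise ValueError("image_size must be positive")
        if self.mel_bands <= 0:
            raise ValueError("mel_bands must be positive")


@dataclass(frozen=True)
class SpectrogramImage:
    """Time x frequency (or mel band) dB matrix plus axes and kind."""

    matrix: np.ndarray  # shape (n_frames, n_bins), dB
    time_axis: np.ndarray  # frame start times, s
    freq_axis: np.ndarray  # Hz, or mel-band index for kind="mel"
    kind: str
    db_floor: float


def _frame_power_spectra(
    segment: AudioSignal, params: SpectroParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rectangular-window framing + per-frame power spectrum |X|^2 / n."""
    n = int(round(segment.rate * params.frame_len_ms / 1000.0))
    hop = max(int(round(n * (1.0 - params.overlap))), 1)
    x = segment.samples
    if x.size < n:
        raise ValueError(f"segment shorter than one {n}-sample frame")
    count = (x.size - n) // hop + 1
    nfft = 1 << int(np.ceil(np.log2(n)))
    idx = np.arange(n)[None, :] + hop * np.arange(count)[:, None]
    frames = x[idx]
    power = np.abs(np.fft.rfft(frames, nfft, axis=1)) ** 2 / n
    times = hop * np.arange(count) / segment.rate
    freqs = np.fft.rfftfreq(nfft, d=1.0 / segment.rate)
    return power, times, freqs


def _to_db(power: np.ndarray, floor: float) -> np.ndarray:
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(power)
    return np.maximum(np.where(np.isfinite(db), db, floor), floor)


def speech_spectrogram(segment: AudioSignal, params: SpectroParams) -> SpectrogramImage:
    """Log-power STFT view (time-frequency amplitude distribution)."""
    power, times, freqs = _frame_power_spectra(segment, params)
    return SpectrogramImage(
        matrix=_to_db(power, params.db_floor),
        time_axis=times,
        freq_axis=freqs,
        kind="speech",
        db_floor=params.db_floor,
    )


def energy_spectrogram(segment: AudioSignal, params: SpectroParams) -> SpectrogramImage:
    """Per-frame spectral energy distribution.

    Each frame's power spectrum is rescaled so its linear-domain bin sum
    equals the frame's mean-square energy, making columns comparable as
    energy distributions while preserving spectral shape.
    """
    n = int(round(segment.rate * params.frame_len_ms / 1000.0))
    hop = max(int(round(n * (1.0 - params.overlap))), 1)
    power, times, freqs = _frame_power_spectra(segment, params)
    count = power.shape[0]
    idx = np.arange(n)[None, :] + hop * np.arange(count)[:, None]
    energies = np.mean(segment.samples[idx] ** 2, axis=1)
    sums = power.sum(axis=1)
    scale = np.where(sums > 0, energies / np.where(sums > 0, sums, 1.0), 0.0)
    return SpectrogramImage(
        matrix=_to_db(power * scale[:, None], params.db_floor),
        time_axis=times,
        freq_axis=freqs,
        kind="energy",
        db_floor=params.db_floor,
    )


def hz_to_mel(f):
    """HTK mel scale: mel(f) = 2595 * log10(1 + f / 700)."""
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(n_bands: int, nfft_bins: int, rate: int) -> np.ndarray:
    """Triangular mel filterbank, shape (n_bands, nfft_bins)."""
    freqs = np.linspace(0.0, rate / 2.0, nfft_bins)
    edges = mel_to_hz(np.linspace(0.0, hz_to_mel(rate / 2.0), n_bands + 2))
    bank = np.zeros((n_bands, nfft_bins))
    for b in range(n_bands):
        lo, mid, hi = edges[b], edges[b + 1], edges[b + 2]
        up = (freqs - lo) / max(mid - lo, 1e-12)
        down = (hi - freqs) / max(hi - mid, 1e-12)
        bank[b] = np.clip(np.minimum(up, down), 0.0, None)
    return bank


def mel_spectrogram(segment: AudioSignal, params: SpectroParams) -> SpectrogramImage:
    """Mel-filterbank energies per frame, log-compressed."""
    power, times, _ = _frame_power_spectra(segment, params)
    bank = mel_filterbank(params.mel_bands, power.shape[1], segment.rate)
    mel_power = power @ bank.T
    return SpectrogramImage(
        matrix=_to_db(mel_power, params.db_floor),
        time_axis=times,
        freq_axis=np.arange(params.mel_bands, dtype=float),
        kind="mel",
        db_floor=params.db_floor,
    )


SPECTROGRAM_FUNCS = {
    "speech": speech_spectrogram,
    "energy": energy_spectrogram,
    "mel": mel_spectrogram,
}


def render_rgb(spec: SpectrogramImage, params: SpectroParams) -> np.ndarray:
    """Color-mapped square RGB array (image_size, image_size, 3), uint8.

    Values are mapped on the absolute scale [db_floor, 0] dB so that
    overall-loudness differences between segments stay visible; frequency
    increases upward (row 0 = highest band).
    """
    norm = (spec.matrix - params.db_floor) / (0.0 - params.db_floor)
    norm = np.clip(norm, 0.0, 1.0)
    cmap = colormaps[params.colormap]
    rgb = (cmap(norm.T[::-1])[:, :, :3] * 255.0).astype(np.uint8)
    img = Image.fromarray(rgb)
    img = img.resize((params.image_size, params.image_size), Image.BILINEAR)
    return np.asarray(img)


def export_image(spec: SpectrogramImage, path: str | Path, params: SpectroParams) -> Path:
    """Write the rendered spectrogram as a JPEG; deterministic per input."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rgb = render_rgb(spec, params)
    Image.fromarray(rgb).save(path, format="JPEG", quality=95)
    return path
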