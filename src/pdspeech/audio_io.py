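"""Single-channel audio I/O and resampling.

All pipeline stages operate on :class:`AudioSignal`: a mono waveform with
dimensionless full-scale amplitudes in [-1, 1] and an explicit sampling rate.
Integer PCM is converted with the symmetric convention ``sample / 2**(bits-1)``
so that a full-scale sine maps to +/-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

__all__ = ["AudioSignal", "read_wav", "write_wav", "resample"]


@dataclass(frozen=True)
class AudioSignal:
    """A mono sampled waveform.

    Parameters
    ----------
    samples
        1-D float array of amplitudes, nominally in [-1, 1].
    rate
        Sampling frequency in Hz, > 0.
    """

    samples: np.ndarray
    rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError(f"samples must be 1-D, got shape {samples.shape}")
        if samples.size < 1:
            raise ValueError("signal must contain at least one sample")
        if not np.all(np.isfinite(samples)):
            raise ValueError("signal contains non-finite samples")
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.samples.size / self.rate

    def __len__(self) -> int:
        return self.samples.size


def read_wav(path: str | Path) -> AudioSignal:
    """Read a PCM or float WAV file as a mono :class:`AudioSignal`.

    Multi-channel input is averaged to mono (one speaker, one device).
    Integer PCM is scaled symmetrically by ``2**(bits-1)``.

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    ValueError
        If the file is not parseable WAV or contains zero samples.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such audio file: {path}")
    try:
        rate, data = wavfile.read(str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # scipy raises bare ValueError on bad RIFF
        raise ValueError(f"not a readable WAV file: {path}: {exc}") from exc
    if data.size == 0:
        raise ValueError(f"zero-length audio: {path}")

    if data.dtype == np.int16:
        samples = data / 2.0**15
    elif data.dtype == np.int32:
        samples = data / 2.0**31
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"unsupported WAV sample format {data.dtype} in {path}")

    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    return AudioSignal(samples=samples, rate=int(rate))


def write_wav(
    signal: AudioSignal,
    path: str | Path,
    *,
    bits: int = 16,
    clip: bool = True,
) -> None:
    """Write ``signal`` as PCM WAV (16-bit default) or 32-bit float.

    Samples outside [-1, 1] are clipped (with a warning) when ``clip`` is
    true, otherwise rejected.
    """
    samples = signal.samples
    peak = np.max(np.abs(samples)) if samples.size else 0.0
    if peak > 1.0:
        if not clip:
            raise ValueError(f"samples exceed full scale (peak {peak:.3f})")
        warnings.warn(
            f"clipping {np.count_nonzero(np.abs(samples) > 1.0)} samples "
            f"outside [-1, 1] (peak {peak:.3f})",
            stacklevel=2,
        )
        samples = np.clip(samples, -1.0, 1.0)

    if bits == 16:
        scaled = np.round(samples * 2.0**15)
        data = np.clip(scaled, -(2.0**15), 2.0**15 - 1).astype(np.int16)
    elif bits == 32:
        data = samples.astype(np.float32)
    else:
        raise ValueError(f"unsupported bit depth {bits} (use 16 or 32)")
    wavfile.write(str(path), signal.rate, data)


def resample(signal: AudioSignal, target_rate: int) -> AudioSignal:
    """Resample with a polyphase anti-aliasing FIR filter.

    The LPC formant stage is sensitive to aliasing, hence the FIR polyphase
    method rather than plain decimation.
    """
    if target_rate <= 0:
        raise ValueError(f"target_rate must be positive, got {target_rate}")
    if target_rate == signal.rate:
        return signal
    ratio = Fraction(int(target_rate), int(signal.rate))
    out = resample_poly(signal.samples, ratio.numerator, ratio.denominator)
    return AudioSignal(samples=out, rate=int(target_rate))
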