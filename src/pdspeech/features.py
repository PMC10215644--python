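"""Acoustic feature battery on extracted speech segments.

Four feature classes, all computed frame-wise on speech segments and pooled
per subject into mean/standard-deviation summaries:

* prosody — intensity I (dB re a configurable reference) and fundamental
  frequency f0 (autocorrelation pitch tracker, voiced frames only);
* time domain — mean absolute value, energy, RMS, zero-crossing count and
  slope-sign-change count per frame;
* frequency domain — frequency of the maximum periodogram component,
  power-weighted average frequency, and the skewness/kurtosis of the
  periodogram value distribution;
* formants — first three vocal-tract resonances from Burg-method LPC at
  16 kHz with 2 ms half-overlapping frames, candidates filtered by root
  bandwidth.

Framing for the first three classes follows 20 ms rectangular windows with
50% overlap; the trailing partial frame is dropped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .audio_io import AudioSignal

__all__ = [
    "FrameSpec",
    "FeatureTrack",
    "FeatureSummary",
    "LPC_FRAME_SPEC",
    "frame_segment",
    "intensity_track",
    "pitch_track",
    "time_features",
    "spectral_features",
    "lpc_formants",
    "summarize_features",
    "DEFAULT_INTENSITY_REF",
]

log = logging.getLogger(__name__)

DEFAULT_INTENSITY_REF = 1e-4  # full-scale amplitude giving 0 dB
DEFAULT_INTENSITY_FLOOR_DB = -40.0
LPC_RATE = 16000


@dataclass(frozen=True)
class FrameSpec:
    """Analysis framing: length in ms, fractional overlap, rectangular window."""

    frame_len_ms: float = 20.0
    overlap: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError("overlap must lie in [0, 1)")
        if self.frame_len_ms <= 0:
            raise ValueError("frame_len_ms must be positive")

    def frame_samples(self, rate: int) -> int:
        return int(round(rate * self.frame_len_ms / 1000.0))

    def hop_samples(self, rate: int) -> int:
        n = self.frame_samples(rate)
        return max(int(round(n * (1.0 - self.overlap))), 1)


LPC_FRAME_SPEC = FrameSpec(frame_len_ms=2.0, overlap=0.5)


@dataclass(frozen=True)
class FeatureTrack:
    """Named per-frame feature values."""

    name: str
    values: np.ndarray
    units: str = ""


@dataclass(frozen=True)
class FeatureSummary:
    """Per-subject mean/sd of every feature, pooled over all speech frames."""

    stats: dict[str, tuple[float, float]] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for name, (mu, sigma) in self.stats.items():
            out[f"mu_{name}"] = mu
            out[f"sd_{name}"] = sigma
        return out


def frame_segment(segment: AudioSignal, spec: FrameSpec = FrameSpec()) -> np.ndarray:
    """Slice a segment into overlapping rectangular frames (rows).

    Frame count is ``floor((N - n) / hop) + 1``; the trailing partial frame
    is dropped.
    """
    n = spec.frame_samples(segment.rate)
    hop = spec.hop_samples(segment.rate)
    x = segment.samples
    if x.size < n:
        raise ValueError(
            f"segment of {x.size} samples shorter than one {n}-sample frame"
        )
    count = (x.size - n) // hop + 1
    idx = np.arange(n)[None, :] + hop * np.arange(count)[:, None]
    return x[idx]


def intensity_track(
    frames: np.ndarray,
    ref: float = DEFAULT_INTENSITY_REF,
    floor_db: float = DEFAULT_INTENSITY_FLOOR_DB,
) -> FeatureTrack:
    """Per-frame intensity I = 20*log10(rms / ref) dB; silent frames -> floor."""
    if frames.size == 0:
        raise ValueError("no frames")
    rms = np.sqrt(np.mean(frames**2, axis=1))
    with np.errstate(divide="ignore"):
        vals = 20.0 * np.log10(rms / ref)
    vals = np.where(rms > 0, vals, floor_db)
    return FeatureTrack("I", np.maximum(vals, floor_db), units="dB")


def pitch_track(
    segment: AudioSignal,
    f0_range: tuple[float, float] = (75.0, 400.0),
    frame_len_ms: float = 40.0,
    hop_ms: float = 20.0,
    voicing_threshold: float = 0.5,
) -> FeatureTrack:
    """Autocorrelation pitch per frame, voiced frames only.

    A frame is voiced when the normalized autocorrelation peak inside the
    period-lag search range exceeds ``voicing_threshold``. The peak lag is
    refined by parabolic interpolation. Unvoiced frames are omitted, so the
    returned track may be empty.
    """
    fmin, fmax = f0_range
    rate = segment.rate
    n = int(round(rate * frame_len_ms / 1000.0))
    hop = int(round(rate * hop_ms / 1000.0))
    lag_min = int(np.floor(rate / fmax))
    lag_max = int(np.ceil(rate / fmin))
    if n <= lag_max:
        raise ValueError(
            f"frame of {n} samples shorter than two periods at {fmin} Hz"
        )
    x = segment.samples
    values = []
    for start in range(0, x.size - n + 1, hop):
        frame = x[start : start + n]
        frame = frame - frame.mean()
        e0 = np.dot(frame, frame)
        if e0 <= 0:
            continue
        # FFT-based autocorrelation
        nfft = 1 << int(np.ceil(np.log2(2 * n)))
        spec = np.fft.rfft(frame, nfft)
        acf = np.fft.irfft(spec * np.conj(spec))[: lag_max + 2]
        acf = acf / acf[0]
        window = acf[lag_min : lag_max + 1]
        k = int(np.argmax(window)) + lag_min
        if acf[k] < voicing_threshold:
            continue
        # parabolic refinement around the peak
        if 1 <= k < acf.size - 1:
            y0, y1, y2 = acf[k - 1], acf[k], acf[k + 1]
            denom = y0 - 2.0 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
        else:
            delta = 0.0
        values.append(rate / (k + delta))
    return FeatureTrack("f0", np.asarray(values), units="Hz")


def time_features(frames: np.ndarray) -> dict[str, FeatureTrack]:
    """Per-frame mav, enrg, rms, ZC and SSC.

    ZC counts strict sign products ``x[i-1] * x[i] < 0``; SSC counts strict
    slope-sign products ``(x[i-1]-x[i-2]) * (x[i]-x[i-1]) < 0``.
    """
    if frames.size == 0:
        raise ValueError("no frames")
    mav = np.mean(np.abs(frames), axis=1)
    enrg = np.mean(frames**2, axis=1)
    rms = np.sqrt(enrg)
    zc = np.sum(frames[:, :-1] * frames[:, 1:] < 0, axis=1).astype(float)
    d = np.diff(frames, axis=1)
    ssc = np.sum(d[:, :-1] * d[:, 1:] < 0, axis=1).astype(float)
    return {
        "mav": FeatureTrack("mav", mav),
        "enrg": FeatureTrack("enrg", enrg),
        "rms": FeatureTrack("rms", rms),
        "ZC": FeatureTrack("ZC", zc, units="count"),
        "SSC": FeatureTrack("SSC", ssc, units="count"),
    }


def spectral_features(frames: np.ndarray, rate: int) -> dict[str, FeatureTrack]:
    """Per-frame periodogram features: maxf, waf, skewness, kurtosis.

    The periodogram runs over positive frequencies of each rectangular
    frame. ``maxf`` is the frequency of the strongest component, ``waf`` the
    P^2-weighted average frequency, and skewness/kurtosis (Pearson, i.e.
    non-excess kurtosis) describe the distribution of periodogram values.
    All-zero frames are excluded and logged.
    """
    if frames.size == 0:
        raise ValueError("no frames")
    n = frames.shape[1]
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    maxf, waf, skw, kur = [], [], [], []
    n_dropped = 0
    for frame in frames:
        spec = np.abs(np.fft.rfft(frame)) ** 2 / n
        total = spec.sum()
        if total <= 0:
            n_dropped += 1
            continue
        maxf.append(freqs[int(np.argmax(spec))])
        w = spec**2
        waf.append(float(np.dot(w, freqs) / w.sum()))
        mu = spec.mean()
        sigma = spec.std()
        if sigma > 0:
            z = (spec - mu) / sigma
            skw.append(float(np.mean(z**3)))
            kur.append(float(np.mean(z**4)))
        else:
            skw.append(0.0)
            kur.append(0.0)
    if n_dropped:
        log.debug("spectral_features: dropped %d all-zero frames", n_dropped)
    return {
        "maxf": FeatureTrack("maxf", np.asarray(maxf), units="Hz"),
        "waf": FeatureTrack("waf", np.asarray(waf), units="Hz"),
        "skw": FeatureTrack("skw", np.asarray(skw)),
        "kur": FeatureTrack("kur", np.asarray(kur)),
    }


def _lpc_coeffs(frame: np.ndarray, order: int) -> np.ndarray | None:
    """Burg-method LPC: returns [1, a1, .., ap] or None if degenerate.

    Burg's lattice recursion estimates the all-pole model from forward and
    backward prediction errors without windowing the frame, which keeps the
    pole estimates usable on the very short (2 ms, 32-sample) frames this
    stage runs on; the classical autocorrelation method is badly biased at
    that frame length.
    """
    a = np.zeros(order + 1)
    a[0] = 1.0
    f = np.asarray(frame, dtype=np.float64)[1:].copy()
    b = np.asarray(frame, dtype=np.float64)[:-1].copy()
    for m in range(1, order + 1):
        denom = np.dot(f, f) + np.dot(b, b)
        if denom <= 0:
            return None
        k = -2.0 * np.dot(f, b) / denom
        a[: m + 1] = a[: m + 1] + k * a[: m + 1][::-1]
        f_new = f + k * b
        b_new = b + k * f
        f = f_new[1:]
        b = b_new[:-1]
    if not np.all(np.isfinite(a)):
        return None
    return a


def lpc_formants(
    segment: AudioSignal,
    spec: FrameSpec = LPC_FRAME_SPEC,
    order: int = 12,
    bandwidth_max: float = 400.0,
) -> np.ndarray:
    """First three formants per analyzable frame, shape (n_frames, 3) in Hz.

    Requires a 16 kHz segment (downsample first). Formant candidates are
    angles of predictor-polynomial roots in the upper half plane, kept when
    the implied bandwidth ``-rate/pi * ln|r|`` is below ``bandwidth_max``;
    the three lowest candidates are reported, ascending. Frames with fewer
    than three candidates (or zero energy) are excluded.
    """
    if segment.rate != LPC_RATE:
        raise ValueError(f"LPC analysis expects {LPC_RATE} Hz, got {segment.rate}")
    frames = frame_segment(segment, spec)
    n = frames.shape[1]
    if order >= n:
        raise ValueError(f"LPC order {order} must be below frame length {n}")
    rate = segment.rate
    rows = []
    n_dropped = 0
    for frame in frames:
        coeffs = _lpc_coeffs(frame, order)
        if coeffs is None:
            n_dropped += 1
            continue
        roots = np.roots(coeffs)
        roots = roots[np.imag(roots) > 0]
        freqs = np.angle(roots) * rate / (2.0 * np.pi)
        with np.errstate(divide="ignore"):
            bws = -rate / np.pi * np.log(np.abs(roots))
        keep = (freqs > 50.0) & (freqs < rate / 2.0 - 50.0) & (bws < bandwidth_max)
        cand = np.sort(freqs[keep])
        if cand.size < 3:
            n_dropped += 1
            continue
        rows.append(cand[:3])
    if n_dropped:
        log.debug("lpc_formants: dropped %d degenerate frames", n_dropped)
    return np.asarray(rows).reshape(-1, 3)


def summarize_features(tracks: dict[str, list[FeatureTrack]]) -> FeatureSummary:
    """Pool per-frame values across all segments and take mean and sample sd.

    ``tracks`` maps feature name to the per-segment tracks of one subject.
    An empty pooled set (e.g. no voiced frames for f0) is recorded as NaN;
    a single value gets sd 0 with a warning.
    """
    stats: dict[str, tuple[float, float]] = {}
    for name, track_list in tracks.items():
        pooled = np.concatenate([t.values for t in track_list]) if track_list else np.array([])
        if pooled.size == 0:
            stats[name] = (float("nan"), float("nan"))
            continue
        mu = float(np.mean(pooled))
        if pooled.size == 1:
            warnings.warn(f"single value for feature {name!r}; sd set to 0", stacklevel=2)
            sigma = 0.0
        else:
            sigma = float(np.std(pooled, ddof=1))
        stats[name] = (mu, sigma)
    return FeatureSummary(stats=stats)
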