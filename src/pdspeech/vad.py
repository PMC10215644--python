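"""Energy-based voice-activity detection and phonological features.

The detector segments the signal into 20 ms non-overlapping rectangular
frames, computes the mean-square energy of each, and labels a frame as
speech when its energy strictly exceeds 1/10 of the maximum frame energy.
Contiguous runs of equal labels become speech/pause segments; "utterings"
are the speech segments. Phonological features (uttering count, pause
count, speech rate, total pause time) are computed on the assessment span
obtained by trimming leading and trailing pauses.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .audio_io import AudioSignal

__all__ = [
    "EnergyTrack",
    "VadResult",
    "PhonologyFeatures",
    "frame_energy",
    "detect_voice_activity",
    "trim_edge_pauses",
    "extract_speech_segments",
    "phonology_features",
    "vad_from_segments",
    "DEFAULT_FRAME_MS",
    "DEFAULT_THRESHOLD_RATIO",
]

DEFAULT_FRAME_MS = 20.0
DEFAULT_THRESHOLD_RATIO = 0.1  # 1/10 of the maximum frame energy


@dataclass(frozen=True)
class EnergyTrack:
    """Per-frame mean-square energy over non-overlapping frames."""

    values: np.ndarray  # energy per frame, amplitude^2 units
    frame_len: int  # samples per frame
    rate: int  # Hz

    @property
    def frame_len_ms(self) -> float:
        return 1000.0 * self.frame_len / self.rate

    @property
    def times(self) -> np.ndarray:
        """Frame start times in seconds."""
        return np.arange(self.values.size) * self.frame_len / self.rate


@dataclass(frozen=True)
class VadResult:
    """Voice-activity decision: energies, threshold, per-frame labels, segments.

    ``segments`` is a list of ``(start_sample, end_sample, label)`` with
    half-open sample intervals tiling the framed span; labels alternate
    between ``"speech"`` and ``"pause"``.
    """

    track: EnergyTrack
    threshold: float
    active: np.ndarray  # bool per frame
    segments: list[tuple[int, int, str]]

    def speech_segments(self) -> list[tuple[int, int]]:
        return [(a, b) for a, b, lab in self.segments if lab == "speech"]

    def pause_segments(self) -> list[tuple[int, int]]:
        return [(a, b) for a, b, lab in self.segments if lab == "pause"]


@dataclass(frozen=True)
class PhonologyFeatures:
    """Uttering/pause counts, speech rate and pause time on the trimmed span."""

    n_uttering: int
    n_pause: int
    r_speech: float  # utterings per minute
    t_pause: float  # seconds

    def as_dict(self) -> dict[str, float]:
        return {
            "n_uttering": self.n_uttering,
            "n_pause": self.n_pause,
            "r_speech_per_min": self.r_speech,
            "t_pause_s": self.t_pause,
        }


def frame_energy(signal: AudioSignal, frame_ms: float = DEFAULT_FRAME_MS) -> EnergyTrack:
    """Mean-square energy per non-overlapping rectangular frame.

    The trailing partial frame is dropped.
    """
    n = int(round(signal.rate * frame_ms / 1000.0))
    if n < 1 or signal.samples.size < n:
        raise ValueError(
            f"signal too short for one {frame_ms:g} ms frame "
            f"({signal.samples.size} samples at {signal.rate} Hz)"
        )
    n_frames = signal.samples.size // n
    frames = signal.samples[: n_frames * n].reshape(n_frames, n)
    values = np.mean(frames**2, axis=1)
    return EnergyTrack(values=values, frame_len=n, rate=signal.rate)


def detect_voice_activity(
    track: EnergyTrack, threshold_ratio: float = DEFAULT_THRESHOLD_RATIO
) -> VadResult:
    """Label frames speech/pause against ``max(energy) * threshold_ratio``.

    Activity requires energy strictly above the threshold, so an all-zero
    signal is all-pause.
    """
    if track.values.size == 0:
        raise ValueError("empty energy track")
    threshold = float(np.max(track.values)) * threshold_ratio
    active = track.values > threshold

    segments: list[tuple[int, int, str]] = []
    n = track.frame_len
    start = 0
    for k in range(1, active.size + 1):
        if k == active.size or active[k] != active[start]:
            label = "speech" if active[start] else "pause"
            segments.append((start * n, k * n, label))
            start = k
    return VadResult(track=track, threshold=threshold, active=active, segments=segments)


def trim_edge_pauses(vad: VadResult) -> VadResult:
    """Drop leading and trailing pause segments (the assessment span).

    Raises
    ------
    ValueError
        If the signal contains no speech at all (unassessable sample).
    """
    labels = [lab for _, _, lab in vad.segments]
    if "speech" not in labels:
        raise ValueError("no speech detected; sample is unassessable")
    first = labels.index("speech")
    last = len(labels) - 1 - labels[::-1].index("speech")
    return replace(vad, segments=vad.segments[first : last + 1])


def extract_speech_segments(signal: AudioSignal, vad: VadResult) -> list[AudioSignal]:
    """Sample-exact sub-signals for every speech segment, in order."""
    out = []
    for a, b in vad.speech_segments():
        out.append(AudioSignal(samples=signal.samples[a:b].copy(), rate=signal.rate))
    return out


def vad_from_segments(
    segments: list[tuple[float, float, str]], rate: int, frame_ms: float = DEFAULT_FRAME_MS
) -> VadResult:
    """Build a VadResult from a known (e.g. ground-truth) segmentation.

    Segment times are in seconds; labels must alternate speech/pause. The
    result carries a frame-level reconstruction of the activity pattern so
    it can stand in wherever a detected VadResult is accepted — in
    particular as the speech/silence reference of the SNR metric when the
    energy detector itself is unreliable (very low SNR).
    """
    n = int(round(rate * frame_ms / 1000.0))
    seg_samples = [
        (int(round(a * rate)), int(round(b * rate)), lab) for a, b, lab in segments
    ]
    total_frames = seg_samples[-1][1] // n if seg_samples else 0
    active = np.zeros(total_frames, dtype=bool)
    for a, b, lab in seg_samples:
        if lab == "speech":
            active[a // n : max(b // n, a // n + 1)] = True
    track = EnergyTrack(values=np.zeros(total_frames), frame_len=n, rate=rate)
    return VadResult(track=track, threshold=0.0, active=active, segments=seg_samples)


def phonology_features(trimmed: VadResult) -> PhonologyFeatures:
    """Phonological features on an edge-trimmed VAD result.

    Counts use the trimmed span: ``n_pause`` counts interior pauses only, and
    the speech rate divides the uttering count by the trimmed-span duration.
    """
    speech = trimmed.speech_segments()
    if not speech:
        raise ValueError("no speech segments in trimmed VAD result")
    pauses = trimmed.pause_segments()
    span_start = trimmed.segments[0][0]
    span_end = trimmed.segments[-1][1]
    span_minutes = (span_end - span_start) / trimmed.track.rate / 60.0
    t_pause = sum(b - a for a, b in pauses) / trimmed.track.rate
    return PhonologyFeatures(
        n_uttering=len(speech),
        n_pause=len(pauses),
        r_speech=len(speech) / span_minutes,
        t_pause=t_pause,
    )
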