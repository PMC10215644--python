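"""Synthetic continuous-speech generator with controllable dysarthric traits.

Source--filter synthesis: a glottal impulse train at the target pitch
(with cycle-to-cycle jitter and a slow intonation drift) plus a weak
aspiration-noise floor, amplitude-modulated, and passed through a cascade
of second-order formant resonators. The impulse source has a flat
spectrum, so the voiced output is genuinely all-pole and the profile's
resonator frequencies are recoverable by LPC analysis — the property the
feature battery is validated against. Utterings alternate with true
silences; white Gaussian ambient noise is added at a controlled SNR,
calibrated so that the speech/silence power-ratio measurement recovers the
requested value. The generator exists because the study cohort it emulates
(continuous ~18 s read speech from Parkinson's patients and healthy
controls) is private: every trait the feature battery measures — pause
structure, loudness and its modulation depth, pitch level and variability,
formant structure — is an explicit, independently verifiable knob.

The default profiles encode the hypokinetic contrasts reported for
Parkinsonian speech: more and longer pauses, ~10 dB lower loudness, and
roughly halved pitch and loudness variability relative to healthy controls,
plus broader high-formant bandwidths (imprecise articulation damps the
upper resonances).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

from .audio_io import AudioSignal, write_wav
from .vad import DEFAULT_FRAME_MS

__all__ = [
    "SynthProfile",
    "GroundTruth",
    "CohortManifest",
    "PD_PROFILE",
    "HC_PROFILE",
    "synth_uttering",
    "synth_speech_sample",
    "make_cohort",
]


@dataclass(frozen=True)
class SynthProfile:
    """Trait profile of one synthetic speaker.

    Durations in seconds (mean, sd pairs), frequencies in Hz, loudness as a
    peak amplitude in (0, 1]; ``noise_snr_db`` is the target speech-band SNR
    of the additive ambient noise (``np.inf`` for a clean signal).
    """

    n_utterings: int = 9
    uttering_dur: tuple[float, float] = (1.4, 0.3)
    pause_dur: tuple[float, float] = (0.5, 0.15)
    f0_mean: float = 170.0
    f0_sd: float = 25.0  # slow intonation drift, Hz
    jitter: float = 0.01  # fractional cycle-to-cycle period perturbation
    loudness: float = 0.5  # peak amplitude
    loudness_sd: float = 0.12  # fractional amplitude-modulation depth
    formants: tuple[tuple[float, float], ...] = (
        (500.0, 80.0),
        (1500.0, 120.0),
        (2500.0, 200.0),
    )
    noise_snr_db: float = 30.0
    aspiration: float = 0.01  # noise floor relative to glottal pulse amplitude
    rate: int = 44100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_utterings < 1:
            raise ValueError("n_utterings must be >= 1")
        if self.uttering_dur[0] <= 0 or self.pause_dur[0] <= 0:
            raise ValueError("durations must be positive")
        if not 0.0 <= self.loudness <= 1.0:
            raise ValueError("loudness must lie in [0, 1]")
        freqs = [f for f, _ in self.formants]
        if any(b <= a for a, b in zip(freqs, freqs[1:])):
            raise ValueError("formant frequencies must be strictly increasing")
        if not np.isfinite(self.noise_snr_db) and self.noise_snr_db < 0:
            raise ValueError("noise_snr_db must be finite or +inf")


# Default class profiles: the PD-like profile has more/longer pauses,
# -10 dB loudness, halved pitch/loudness variability, slightly lower pitch,
# and broader upper-formant bandwidths than the HC-like profile.
HC_PROFILE = SynthProfile()
PD_PROFILE = SynthProfile(
    n_utterings=13,
    uttering_dur=(0.9, 0.25),
    pause_dur=(0.65, 0.2),
    f0_mean=155.0,
    f0_sd=12.0,
    loudness=0.158,  # -10 dB vs 0.5
    loudness_sd=0.06,
    formants=((500.0, 120.0), (1500.0, 300.0), (2500.0, 500.0)),
)


@dataclass(frozen=True)
class GroundTruth:
    """Exact construction record of a synthetic sample."""

    segments: list[tuple[float, float, str]]  # (start s, end s, speech|pause)
    f0_tracks: list[np.ndarray]  # per-uttering cycle-wise pitch, Hz
    clean: AudioSignal

    def speech_segments(self) -> list[tuple[float, float]]:
        return [(a, b) for a, b, lab in self.segments if lab == "speech"]

    def __post_init__(self) -> None:
        labs = [lab for _, _, lab in self.segments]
        if any(a == b for a, b in zip(labs, labs[1:])):
            raise ValueError("segment labels must alternate")


def _resonator_coeffs(freq: float, bandwidth: float, rate: int):
    """Second-order all-pole resonator (unit DC-normalized numerator)."""
    r = np.exp(-np.pi * bandwidth / rate)
    theta = 2.0 * np.pi * freq / rate
    a = np.array([1.0, -2.0 * r * np.cos(theta), r * r])
    return np.array([np.sum(a)]), a  # unity gain at DC


def synth_uttering(
    profile: SynthProfile, duration: float, rng: np.random.Generator
) -> tuple[AudioSignal, np.ndarray]:
    """Synthesize one voiced uttering of ``duration`` seconds.

    Returns the signal and the cycle-wise intended f0 track (Hz).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rate = profile.rate
    nyquist = rate / 2.0
    for f, _ in profile.formants:
        if f >= nyquist:
            raise ValueError(f"formant {f} Hz at or above Nyquist ({nyquist} Hz)")
    n = int(round(duration * rate))
    if profile.loudness == 0.0:
        return AudioSignal(np.zeros(max(n, 1)), rate), np.array([])

    # slow intonation drift: smoothed random walk scaled to f0_sd
    n_ctrl = max(int(np.ceil(duration * 4)) + 2, 4)  # ~4 control points / s
    drift = np.cumsum(rng.standard_normal(n_ctrl))
    drift -= drift.mean()
    sd = drift.std()
    if sd > 0 and profile.f0_sd > 0:
        drift = drift / sd * profile.f0_sd
    else:
        drift = np.zeros(n_ctrl)
    ctrl_t = np.linspace(0.0, duration, n_ctrl)

    # glottal source: impulse train with jittered periods + aspiration floor
    source = np.zeros(n)
    f0_track = []
    t = 0.0
    while True:
        f0_t = profile.f0_mean + np.interp(t, ctrl_t, drift)
        f0_t = max(f0_t, 40.0)
        f0_t *= 1.0 + profile.jitter * rng.standard_normal()
        period = 1.0 / f0_t
        idx = int(round(t * rate))
        if idx >= n:
            break
        source[idx] += 1.0
        f0_track.append(f0_t)
        t += period
    if profile.aspiration > 0:
        source += profile.aspiration * rng.standard_normal(n)

    # vocal-tract filter: cascade of formant resonators
    out = source
    for freq, bw in profile.formants:
        b, a = _resonator_coeffs(freq, bw, rate)
        out = lfilter(b, a, out)

    # slow amplitude modulation (loudness_sd = fractional depth); excursion
    # clipped to +/-2 sd so the voiced energy never collapses toward silence
    if profile.loudness_sd > 0:
        z = np.clip(rng.standard_normal(n_ctrl), -2.0, 2.0)
        am_ctrl = 1.0 + profile.loudness_sd * z
        am = np.interp(np.arange(n) / rate, ctrl_t, am_ctrl)
        out = out * am

    # fade edges to avoid clicks (5 ms raised cosine)
    edge = min(int(0.005 * rate), n // 4)
    if edge > 1:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(edge) / edge))
        out[:edge] *= ramp
        out[-edge:] *= ramp[::-1]

    peak = np.max(np.abs(out))
    if peak > 0:
        out = out * (profile.loudness / peak)
    return AudioSignal(out, rate), np.asarray(f0_track)


def synth_speech_sample(profile: SynthProfile) -> tuple[AudioSignal, GroundTruth]:
    """Synthesize a full continuous-speech sample: utterings, pauses, noise.

    The sample starts and ends with an edge pause, so the ground truth holds
    ``n_utterings`` speech segments and ``n_utterings - 1`` internal pauses.
    Segment durations are quantized to the 20 ms analysis frame grid so the
    ground-truth segmentation is exactly representable by a frame-based
    voice-activity detector. Noise power is calibrated so the speech/silence
    power-ratio SNR measured on the ground-truth segmentation equals
    ``noise_snr_db``.
    """
    rng = np.random.default_rng(profile.seed)
    rate = profile.rate
    grid = int(round(rate * DEFAULT_FRAME_MS / 1000.0))  # samples per frame

    def _dur(mean_sd: tuple[float, float], min_frames: int = 2) -> float:
        m, s = mean_sd
        dur = float(np.clip(rng.normal(m, s), 0.25 * m, 4.0 * m))
        frames = max(int(round(dur * rate / grid)), min_frames)
        return frames * grid / rate

    pieces: list[np.ndarray] = []
    segments: list[tuple[float, float, str]] = []
    f0_tracks: list[np.ndarray] = []
    t = 0.0

    def _add_pause(dur: float) -> None:
        nonlocal t
        n = int(round(dur * rate))
        pieces.append(np.zeros(n))
        segments.append((t, t + n / rate, "pause"))
        t += n / rate

    _add_pause(_dur(profile.pause_dur))
    for k in range(profile.n_utterings):
        sig, f0s = synth_uttering(profile, _dur(profile.uttering_dur), rng)
        pieces.append(sig.samples)
        segments.append((t, t + len(sig) / rate, "speech"))
        t += len(sig) / rate
        f0_tracks.append(f0s)
        if k < profile.n_utterings - 1:
            _add_pause(_dur(profile.pause_dur))
    _add_pause(_dur(profile.pause_dur))

    clean = np.concatenate(pieces)
    truth = GroundTruth(
        segments=segments, f0_tracks=f0_tracks, clean=AudioSignal(clean, rate)
    )

    if np.isinf(profile.noise_snr_db):
        return AudioSignal(clean.copy(), rate), truth

    # Calibrate noise variance so the measured speech/silence power ratio on
    # the noisy signal equals the target: (P_speech + v) / v = 10^(snr/10).
    speech_mask = np.zeros(clean.size, dtype=bool)
    for a, b, lab in segments:
        if lab == "speech":
            speech_mask[int(round(a * rate)) : int(round(b * rate))] = True
    p_speech = np.mean(clean[speech_mask] ** 2)
    ratio = 10.0 ** (profile.noise_snr_db / 10.0)
    if ratio <= 1.0:
        raise ValueError("noise_snr_db must exceed 0 dB for this noise model")
    var = p_speech / (ratio - 1.0)
    noise = rng.normal(0.0, np.sqrt(var), clean.size)
    return AudioSignal(clean + noise, rate), truth


@dataclass(frozen=True)
class CohortManifest:
    """Subject table: id, class label, WAV path, per-subject seed."""

    rows: list[dict] = field(default_factory=list)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["subject_id", "label", "path", "seed"])
            writer.writeheader()
            for row in self.rows:
                writer.writerow(row)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CohortManifest":
        with open(path, newline="") as fh:
            rows = [
                {**row, "seed": int(row["seed"])} for row in csv.DictReader(fh)
            ]
        return cls(rows=rows)

    def __len__(self) -> int:
        return len(self.rows)


def make_cohort(
    n_pd: int,
    n_hc: int,
    out_dir: str | Path,
    pd_profile: SynthProfile = PD_PROFILE,
    hc_profile: SynthProfile = HC_PROFILE,
    seed: int = 0,
    write_audio: bool = True,
) -> tuple[CohortManifest, dict[str, GroundTruth]]:
    """Generate a labeled synthetic cohort, deterministic under ``seed``.

    Per-subject seeds are derived as ``seed * 10000 + index`` so the cohort
    is reproducible subject-by-subject. Returns the manifest and the
    ground-truth record per subject id.
    """
    if n_pd < 1 or n_hc < 1:
        raise ValueError("need at least one subject per class")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    truths: dict[str, GroundTruth] = {}
    plan = [("PD", pd_profile, i) for i in range(n_pd)] + [
        ("HC", hc_profile, i) for i in range(n_hc)
    ]
    for j, (label, profile, i) in enumerate(plan):
        subj_seed = seed * 10000 + j
        subj_id = f"{label}{i + 1:02d}"
        prof = replace(profile, seed=subj_seed)
        signal, truth = synth_speech_sample(prof)
        wav_path = out_dir / f"{subj_id}.wav"
        if write_audio:
            write_wav(signal, wav_path)
        truths[subj_id] = truth
        rows.append(
            {"subject_id": subj_id, "label": label, "path": str(wav_path), "seed": subj_seed}
        )
    manifest = CohortManifest(rows=rows)
    manifest.to_csv(out_dir / "manifest.csv")
    return manifest, truths
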