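"""End-to-end dual-condition assessment, dataset reduction, classification.

``run_assessment`` applies, to every cohort subject, the identical analysis
on the original and the Wiener-filtered signal: voice-activity detection,
edge-pause trimming, phonological features, the full acoustic feature
battery on the extracted utterings, and the three spectrogram kinds per
uttering exported as JPEG images. Outputs are a per-(subject, condition)
feature table, an enhancement-metrics table and an image manifest.

``reduce_dataset`` re-implements the subject-exclusion step: a subject is
dropped when any configured phonological feature falls outside its own
class's mean +/- k*sd interval computed from the cohort feature table; all
of that subject's spectrogram images leave the image manifest.

``run_classification`` trains and evaluates one CNN per requested
(spectrogram kind, condition) cell and writes the per-cell accuracy / FP /
FN / loss summary.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .audio_io import AudioSignal, read_wav, resample
from .classifier import EvalResult, TrainConfig, build_model, evaluate, split_dataset, train
from .config import PipelineConfig
from .features import (
    FrameSpec,
    frame_segment,
    intensity_track,
    lpc_formants,
    pitch_track,
    spectral_features,
    summarize_features,
    time_features,
)
from .spectro import SPECTROGRAM_FUNCS, SpectroParams, export_image
from .synthvoice import CohortManifest
from .vad import (
    detect_voice_activity,
    extract_speech_segments,
    frame_energy,
    phonology_features,
    trim_edge_pauses,
)
from .wiener import EnhancementMetrics, mse, snr_db, wiener_filter

__all__ = [
    "assess_signal",
    "run_assessment",
    "reduce_dataset",
    "run_classification",
    "PHONOLOGY_COLUMNS",
]

log = logging.getLogger(__name__)

PHONOLOGY_COLUMNS = ("n_uttering", "n_pause", "r_speech_per_min", "t_pause_s")


def assess_signal(signal: AudioSignal, config: PipelineConfig) -> dict[str, float]:
    """Full feature battery for one signal in one condition.

    Returns a flat dict: phonology plus mu/sd of every pooled feature.
    """
    fs = config.features
    vad = detect_voice_activity(
        frame_energy(signal, config.vad.frame_len_ms), config.vad.threshold_ratio
    )
    trimmed = trim_edge_pauses(vad)
    row: dict[str, float] = dict(phonology_features(trimmed).as_dict())

    segments = extract_speech_segments(signal, trimmed)
    spec = FrameSpec(frame_len_ms=fs.frame_len_ms, overlap=fs.overlap)
    tracks: dict[str, list] = {
        name: [] for name in
        ("I", "f0", "mav", "enrg", "rms", "ZC", "SSC", "maxf", "waf", "skw", "kur")
    }
    formant_rows = []
    for seg in segments:
        frames = frame_segment(seg, spec)
        tracks["I"].append(intensity_track(frames, ref=fs.intensity_ref))
        for name, track in time_features(frames).items():
            tracks[name].append(track)
        for name, track in spectral_features(frames, seg.rate).items():
            tracks[name].append(track)
        try:
            tracks["f0"].append(pitch_track(seg, (fs.f0_min, fs.f0_max)))
        except ValueError:
            pass  # uttering shorter than the pitch analysis window
        seg16 = resample(seg, fs.lpc_rate)
        try:
            f123 = lpc_formants(seg16, order=fs.lpc_order, bandwidth_max=fs.lpc_bandwidth_max)
        except ValueError:
            f123 = np.empty((0, 3))
        if f123.size:
            formant_rows.append(f123)
    summary = summarize_features(tracks)
    row.update(summary.as_dict())
    formants = np.concatenate(formant_rows) if formant_rows else np.empty((0, 3))
    for i, name in enumerate(("f1", "f2", "f3")):
        if formants.shape[0] > 1:
            row[f"mu_{name}"] = float(np.mean(formants[:, i]))
            row[f"sd_{name}"] = float(np.std(formants[:, i], ddof=1))
        else:
            row[f"mu_{name}"] = float("nan")
            row[f"sd_{name}"] = float("nan")
    return row


def _export_segment_images(
    signal: AudioSignal,
    config: PipelineConfig,
    image_dir: Path,
    subject_id: str,
    label: str,
    condition: str,
) -> list[dict]:
    vad = detect_voice_activity(
        frame_energy(signal, config.vad.frame_len_ms), config.vad.threshold_ratio
    )
    trimmed = trim_edge_pauses(vad)
    rows = []
    for idx, seg in enumerate(extract_speech_segments(signal, trimmed)):
        for kind in config.spectrogram_kinds:
            params = SpectroParams(
                kind=kind,
                frame_len_ms=config.spectro.frame_len_ms,
                overlap=config.spectro.overlap,
                mel_bands=config.spectro.mel_bands,
                db_floor=config.spectro.db_floor,
                image_size=config.spectro.image_size,
                colormap=config.spectro.colormap,
            )
            spec = SPECTROGRAM_FUNCS[kind](seg, params)
            path = image_dir / condition / label / f"{subject_id}_{idx:03d}_{kind}.jpg"
            export_image(spec, path, params)
            rows.append(
                {
                    "path": str(path),
                    "subject_id": subject_id,
                    "label": label,
                    "condition": condition,
                    "kind": kind,
                    "segment_idx": idx,
                }
            )
    return rows


def run_assessment(
    manifest: CohortManifest,
    out_dir: str | Path,
    config: PipelineConfig = PipelineConfig(),
    export_images: bool = True,
) -> dict[str, pd.DataFrame]:
    """Assess every subject in both conditions; write CSV reports.

    Per-subject failures are logged and skipped; raises only if every
    subject fails. Returns the features, enhancement and image-manifest
    tables (also written to ``out_dir``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    image_dir = out_dir / "images"
    feature_rows, enh_rows, image_rows = [], [], []
    n_failed = 0
    for row in manifest.rows:
        subject_id, label = row["subject_id"], row["label"]
        try:
            original = read_wav(row["path"])
            filtered, _ = wiener_filter(original, config.wiener)

            vad_o = detect_voice_activity(
                frame_energy(original, config.vad.frame_len_ms), config.vad.threshold_ratio
            )
            vad_f = detect_voice_activity(
                frame_energy(filtered, config.vad.frame_len_ms), config.vad.threshold_ratio
            )
            snr_o = snr_db(original, vad_o)
            snr_f = snr_db(filtered, vad_f)
            metrics = EnhancementMetrics(
                snr_original_db=snr_o,
                snr_filtered_db=snr_f,
                snri_db=snr_f - snr_o,
                mse=mse(original, filtered),
            )
            enh_rows.append({"subject_id": subject_id, "label": label, **metrics.as_dict()})

            for condition, signal in (("original", original), ("filtered", filtered)):
                feats = assess_signal(signal, config)
                feature_rows.append(
                    {"subject_id": subject_id, "label": label, "condition": condition, **feats}
                )
                if export_images:
                    image_rows += _export_segment_images(
                        signal, config, image_dir, subject_id, label, condition
                    )
            log.info("assessed %s (%s)", subject_id, label)
        except Exception:
            n_failed += 1
            log.exception("assessment failed for subject %s; skipping", subject_id)
    if n_failed == len(manifest.rows):
        raise RuntimeError("assessment failed for every subject")

    features = pd.DataFrame(feature_rows)
    enhancement = pd.DataFrame(enh_rows)
    images = pd.DataFrame(image_rows)
    features.to_csv(out_dir / "features.csv", index=False)
    enhancement.to_csv(out_dir / "enhancement.csv", index=False)
    if export_images:
        images.to_csv(out_dir / "image_manifest.csv", index=False)
    return {"features": features, "enhancement": enhancement, "images": images}


def reduce_dataset(
    features: pd.DataFrame,
    images: pd.DataFrame,
    k: float = 1.0,
    feature_names: tuple[str, ...] = PHONOLOGY_COLUMNS,
    condition: str = "original",
    compare_to: str = "own",
) -> tuple[list[str], pd.DataFrame, pd.DataFrame]:
    """Exclude subjects whose phonology leaves the class mean +/- k*sd range.

    Intervals are computed per class from the cohort's own feature table in
    the given condition; ``compare_to="opposite"`` checks each subject
    against the other class's interval instead. Returns the excluded
    subject ids, the per-subject decision table, and the reduced image
    manifest.
    """
    sub = features[features["condition"] == condition] if "condition" in features else features
    classes = sorted(sub["label"].unique())
    intervals = {
        lab: {
            name: (
                grp[name].mean() - k * grp[name].std(ddof=1),
                grp[name].mean() + k * grp[name].std(ddof=1),
            )
            for name in feature_names
        }
        for lab, grp in sub.groupby("label")
    }
    decisions = []
    excluded = []
    for _, row in sub.iterrows():
        ref = row["label"]
        if compare_to == "opposite":
            ref = next(lab for lab in classes if lab != row["label"])
        outside = [
            name
            for name in feature_names
            if not (intervals[ref][name][0] <= row[name] <= intervals[ref][name][1])
        ]
        decisions.append(
            {
                "subject_id": row["subject_id"],
                "label": row["label"],
                "excluded": bool(outside),
                "outside_features": ";".join(outside),
            }
        )
        if outside:
            excluded.append(row["subject_id"])
            log.info("excluding %s: %s outside %s range", row["subject_id"], outside, ref)
    reduced = images[~images["subject_id"].isin(excluded)].reset_index(drop=True)
    if reduced.empty:
        raise ValueError("reduction excluded every image")
    return excluded, pd.DataFrame(decisions), reduced


def run_classification(
    images: pd.DataFrame,
    config: TrainConfig,
    out_dir: str | Path | None = None,
    kinds: tuple[str, ...] = ("speech", "energy", "mel"),
    conditions: tuple[str, ...] = ("original", "filtered"),
    subject_grouped: bool = False,
) -> dict[tuple[str, str], EvalResult]:
    """Train and evaluate one model per (kind, condition) cell."""
    results: dict[tuple[str, str], EvalResult] = {}
    summary_rows = []
    for kind in kinds:
        for condition in conditions:
            cell = images[(images["kind"] == kind) & (images["condition"] == condition)]
            if cell.empty:
                raise ValueError(f"no images for kind={kind}, condition={condition}")
            items = list(zip(cell["path"], cell["label"]))
            subjects = list(cell["subject_id"]) if subject_grouped else None
            split = split_dataset(items, seed=config.seed, subjects=subjects)
            model = build_model(
                input_size=config.input_size,
                width_multiplier=config.width_multiplier,
                seed=config.seed,
            )
            history = train(model, split, config)
            result = evaluate(model, split.test, history=history)
            results[(kind, condition)] = result
            summary_rows.append(
                {"kind": kind, "condition": condition, **result.as_dict()}
            )
            log.info(
                "cell (%s, %s): accuracy %.3f loss %.3f", kind, condition,
                result.accuracy, result.loss,
            )
            if out_dir is not None:
                out_dir = Path(out_dir)
                out_dir.mkdir(parents=True, exist_ok=True)
                result.save(out_dir / f"eval_{kind}_{condition}.json")
    if out_dir is not None:
        pd.DataFrame(summary_rows).to_csv(Path(out_dir) / "classification_summary.csv", index=False)
    return results
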