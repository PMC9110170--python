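"""End-to-end wiring: cohort on disk -> feature dataset -> evaluation report."""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from mindfuse.audio import (
    extract_voice_features,
    read_wav,
    segment_audio,
    wiener_denoise,
)
from mindfuse.classify import INDICATORS
from mindfuse.errors import InsufficientDataError
from mindfuse.evaluate import FeatureDataset, cross_validate
from mindfuse.fusion import AttentionConfig
from mindfuse.keypoints import (
    KeypointSequence,
    interpolate_missing,
    keypoint_channel_series,
    read_keypoints,
    segment_sequence,
)
from mindfuse.stats import DEFAULT_STATS, ModalFeatureMatrix, build_modal_feature_matrix
from mindfuse.synth import SubjectData

logger = logging.getLogger(__name__)


def _keypoint_matrix(
    seq: KeypointSequence, stats, conf_threshold: float
) -> ModalFeatureMatrix:
    """Average the per-segment feature matrices of one keypoint stream."""
    seq = interpolate_missing(seq, conf_threshold)
    segments = segment_sequence(seq) or [seq]
    mats = [
        build_modal_feature_matrix(keypoint_channel_series(s), stats)
        for s in segments
    ]
    first = mats[0]
    return ModalFeatureMatrix(
        modality=first.modality,
        matrix=np.mean([m.matrix for m in mats], axis=0),
        channel_ids=first.channel_ids,
        stat_names=first.stat_names,
    )


def _voice_matrix(
    waves, sample_rate: float, stats, denoise: bool, audio_kwargs
) -> ModalFeatureMatrix:
    """Average the per-1s-segment feature matrices of the voice recordings."""
    mats = []
    for wave in waves:
        samples = wiener_denoise(wave, sample_rate) if denoise else np.asarray(wave)
        segments = segment_audio(samples, sample_rate)
        for seg in segments:
            _, channels = extract_voice_features(seg, **audio_kwargs)
            mats.append(build_modal_feature_matrix(channels, stats))
    if not mats:
        raise InsufficientDataError("no usable voice segments for this subject")
    first = mats[0]
    return ModalFeatureMatrix(
        modality="voice",
        matrix=np.mean([m.matrix for m in mats], axis=0),
        channel_ids=first.channel_ids,
        stat_names=first.stat_names,
    )


def extract_subject_features(
    face: KeypointSequence,
    gait: KeypointSequence,
    voice_waves,
    sample_rate: float,
    stats=DEFAULT_STATS,
    conf_threshold: float = 0.1,
    denoise: bool = True,
    audio_kwargs: dict | None = None,
) -> tuple[ModalFeatureMatrix, ModalFeatureMatrix, ModalFeatureMatrix]:
    """(face, voice, gait) feature matrices for one subject."""
    audio_kwargs = dict(audio_kwargs or {})
    return (
        _keypoint_matrix(face, stats, conf_threshold),
        _voice_matrix(voice_waves, sample_rate, stats, denoise, audio_kwargs),
        _keypoint_matrix(gait, stats, conf_threshold),
    )


def build_feature_dataset(
    subjects: list[SubjectData],
    sample_rate: float,
    stats=DEFAULT_STATS,
    conf_threshold: float = 0.1,
    denoise: bool = True,
    audio_kwargs: dict | None = None,
) -> FeatureDataset:
    """Extract features for every subject and stack them into a dataset."""
    faces, voices, gaits, labels = [], [], [], []
    for sub in subjects:
        f, v, g = extract_subject_features(
            sub.face,
            sub.gait,
            sub.voice,
            sample_rate,
            stats=stats,
            conf_threshold=conf_threshold,
            denoise=denoise,
            audio_kwargs=audio_kwargs,
        )
        faces.append(f.matrix)
        voices.append(v.matrix)
        gaits.append(g.matrix)
        labels.append(sub.labels)
    return FeatureDataset(
        blocks={
            "face": np.stack(faces),
            "voice": np.stack(voices),
            "gait": np.stack(gaits),
        },
        labels=np.stack(labels),
        stat_names=tuple(stats),
    )


def load_cohort(cohort_dir) -> tuple[list[SubjectData], dict]:
    """Read a cohort written by :func:`mindfuse.synth.generate_cohort`."""
    root = Path(cohort_dir)
    manifest_path = root / "manifest.json"
    labels_path = root / "labels.csv"
    missing = [str(p) for p in (manifest_path, labels_path) if not p.exists()]
    if missing:
        raise FileNotFoundError(
            f"cohort directory {root} is missing {missing}; expected the "
            "manifest.json/labels.csv/subjects/ layout"
        )
    manifest = json.loads(manifest_path.read_text())
    fps = manifest["spec"]["fps"]
    lines = labels_path.read_text().strip().splitlines()
    header = lines[0].split(",")[1:]
    if list(header) != list(INDICATORS):
        raise ValueError(f"{labels_path}: label columns do not match indicators")
    subjects = []
    for line in lines[1:]:
        parts = line.split(",")
        sid = parts[0]
        labels = np.asarray([int(v) for v in parts[1:]], dtype=int)
        subj_dir = root / "subjects"
        face = read_keypoints(subj_dir / f"{sid}_face.json", "face", fps)
        gait = read_keypoints(subj_dir / f"{sid}_gait.json", "gait", fps)
        waves = []
        i = 0
        while (subj_dir / f"{sid}_voice{i}.wav").exists():
            samples, _ = read_wav(subj_dir / f"{sid}_voice{i}.wav")
            waves.append(samples)
            i += 1
        if not waves:
            raise FileNotFoundError(f"no voice recordings found for subject {sid}")
        subjects.append(
            SubjectData(subject_id=sid, face=face, gait=gait, voice=waves, labels=labels)
        )
    return subjects, manifest


def run_pipeline(config: dict, data_dir, out_dir):
    """Full run: load cohort, extract, fuse, cross-validate, write artifacts.

    Returns the :class:`EvalReport`; writes report.csv, report.json, the
    effective config and run.log into ``out_dir``.
    """
    from mindfuse.config import dump_config  # local import to avoid a cycle

    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects, manifest = load_cohort(data_dir)
    sample_rate = manifest["spec"]["sample_rate"]
    audio_cfg = config["audio"]
    audio_kwargs = {
        "frame_len": audio_cfg["frame_ms"] / 1000.0,
        "hop": audio_cfg["hop_ms"] / 1000.0,
        "preemphasis": audio_cfg["preemphasis"],
        "n_fft": audio_cfg["n_fft"],
        "n_mel": audio_cfg["n_mel"],
        "pitch_band": tuple(audio_cfg["pitch_band"]),
    }
    dataset = build_feature_dataset(
        subjects,
        sample_rate,
        stats=tuple(config["stats"]["set"]),
        denoise=audio_cfg["denoise"],
        audio_kwargs=audio_kwargs,
    )
    attention_config = AttentionConfig(
        similarity=config["fusion"]["similarity"],
        temperature=config["fusion"]["temperature"],
    )
    report = cross_validate(
        dataset,
        condition=config["eval"]["condition"],
        k=config["eval"]["k"],
        seed=config["eval"]["seed"],
        C=config["svm"]["C"],
        sigma_rule=config["svm"]["sigma_rule"],
        attention_config=attention_config,
    )
    report.to_frame().to_csv(out / "report.csv")
    summary = report.to_dict()
    (out / "report.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    dump_config(config, out / "config_used.yaml")
    (out / "run.log").write_text(
        "\n".join(
            [
                f"subjects: {len(subjects)}",
                f"condition: {report.condition}",
                f"overall_accuracy: {report.overall_accuracy:.6f}",
                f"overall_f1: {report.overall_f1:.6f}",
                f"elapsed_s: {time.time() - t0:.1f}",
            ]
        )
        + "\n"
    )
    logger.info("pipeline finished in %.1fs", time.time() - t0)
    return report
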