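"""Synthetic multimodal cohort generator.

Produces keypoint streams (face 68 / gait 18 points), source-filter voice
waveforms and ten binary indicator labels with controllable per-indicator,
per-modality effect sizes, so the full pipeline is testable without any
external data.

Effect wiring (documented in the manifest of every generated cohort):

* labels are independent Bernoulli draws per indicator;
* face: each indicator owns a disjoint block of six landmarks (indicator i
  -> points 6i..6i+5); a positive label adds ``effect * 0.3`` pixels of
  oscillation amplitude to that block (0.3 px = between-subject amplitude
  SD, so effects are standardized shifts);
* gait: indicator i owns joint i; a positive label adds ``effect * 0.4``
  pixels of amplitude to it;
* voice: a positive label shifts the subject's fundamental frequency by
  ``effect * 5 Hz * (i + 1) / 5.5`` (5 Hz = between-subject f0 SD; the
  indicator-specific factor keeps shifts distinguishable).

All randomness flows from a single seed via spawned child generators, so
identical specs produce byte-identical cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

from mindfuse.audio import write_wav
from mindfuse.classify import INDICATORS
from mindfuse.keypoints import POINTS_PER_FRAME, KeypointSequence, write_keypoints_json

MODALITY_COLUMNS = ("face", "voice", "gait")

# between-subject SDs of the generative parameters (units of one "effect")
FACE_AMP_SD = 0.3
GAIT_AMP_SD = 0.4
F0_SD = 5.0

FACE_BASE_AMP = 1.5
GAIT_BASE_AMP = 2.0
F0_BASE = 120.0
DEFAULT_FORMANTS = (700.0, 1200.0, 2600.0)
FORMANT_BANDWIDTH = 80.0


def _default_noise_sd():
    return {"face": 0.3, "gait": 0.4, "voice": 0.02}


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort."""

    n_subjects: int = 40
    prevalence: object = 0.5
    effects: object = 0.0
    noise_sd: dict = field(default_factory=_default_noise_sd)
    fps: float = 25.0
    sample_rate: int = 16000
    seed: int = 0
    face_duration: float = 30.0
    gait_duration: float = 8.0
    voice_segments: int = 3
    voice_duration: float = 1.0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be at least 2")
        prev = np.broadcast_to(
            np.asarray(self.prevalence, dtype=float), (len(INDICATORS),)
        ).copy()
        if np.any(prev <= 0) or np.any(prev >= 1):
            raise ValueError("prevalences must lie strictly inside (0, 1)")
        self.prevalence = prev
        eff = np.asarray(self.effects, dtype=float)
        if eff.ndim == 0:
            eff = np.full((len(INDICATORS), 3), float(eff))
        if eff.shape != (len(INDICATORS), 3):
            raise ValueError(
                f"effects must be scalar or ({len(INDICATORS)}, 3) "
                "(columns: face, voice, gait)"
            )
        self.effects = eff
        if self.fps <= 0 or self.sample_rate <= 0:
            raise ValueError("fps and sample_rate must be positive")

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "prevalence": list(map(float, self.prevalence)),
            "effects": self.effects.tolist(),
            "noise_sd": dict(self.noise_sd),
            "fps": self.fps,
            "sample_rate": self.sample_rate,
            "seed": self.seed,
            "face_duration": self.face_duration,
            "gait_duration": self.gait_duration,
            "voice_segments": self.voice_segments,
            "voice_duration": self.voice_duration,
        }


@dataclass
class SubjectData:
    subject_id: str
    face: KeypointSequence
    gait: KeypointSequence
    voice: list
    labels: np.ndarray


def synthesize_voice(
    f0: float,
    formants=DEFAULT_FORMANTS,
    duration: float = 1.0,
    sample_rate: int = 16000,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Glottal pulse train through an all-pole resonator cascade.

    Impulses are placed with fractional-delay interpolation so the pulse
    period is exact even when sr/f0 is not an integer.  The clean signal
    is peak-normalized to 0.9 before white noise is added.
    """
    if not 50.0 <= f0 <= 500.0:
        raise ValueError(f"f0={f0} outside the supported 50-500 Hz range")
    formants = tuple(float(f) for f in formants)
    if any(b <= a for a, b in zip(formants, formants[1:])):
        raise ValueError("formants must be strictly ascending")
    if formants and formants[-1] >= sample_rate / 2:
        raise ValueError("formants must lie below Nyquist")
    n = int(round(duration * sample_rate))
    x = np.zeros(n + 1)
    pos = np.arange(0.0, n - 1, sample_rate / f0)
    base = pos.astype(int)
    frac = pos - base
    np.add.at(x, base, 1.0 - frac)
    np.add.at(x, base + 1, frac)
    x = x[:n]
    for fc in formants:
        r = np.exp(-np.pi * FORMANT_BANDWIDTH / sample_rate)
        theta = 2.0 * np.pi * fc / sample_rate
        x = lfilter([1.0], [1.0, -2.0 * r * np.cos(theta), r * r], x)
    peak = np.abs(x).max()
    if peak > 0:
        x = x / peak * 0.9
    if noise_sd > 0:
        if rng is None:
            raise ValueError("rng required when noise_sd > 0")
        x = x + rng.normal(0.0, noise_sd, n)
    return x


def generate_keypoint_motion(
    modality: str,
    base_pose: np.ndarray,
    motion_amp,
    motion_freq: float,
    noise_sd: float,
    duration: float,
    fps: float,
    rng: np.random.Generator,
) -> KeypointSequence:
    """Sinusoidal oscillation of each point about its base position.

    Every point moves along its own random unit direction with a random
    phase, at amplitude ``motion_amp`` (scalar or per-point), plus
    Gaussian jitter.  Confidences are drawn uniformly from [0.6, 1.0].
    """
    if duration <= 0 or fps <= 0:
        raise ValueError("duration and fps must be positive")
    n_points = POINTS_PER_FRAME[modality]
    base_pose = np.asarray(base_pose, dtype=float)
    if base_pose.shape != (n_points, 2):
        raise ValueError(f"base_pose must be ({n_points}, 2)")
    amp = np.broadcast_to(np.asarray(motion_amp, dtype=float), (n_points,))
    n_frames = int(round(duration * fps))
    t = np.arange(n_frames) / fps
    phase = rng.uniform(0.0, 2.0 * np.pi, n_points)
    angle = rng.uniform(0.0, 2.0 * np.pi, n_points)
    direction = np.stack([np.cos(angle), np.sin(angle)], axis=1)  # (P, 2)
    osc = amp[None, :] * np.sin(
        2.0 * np.pi * motion_freq * t[:, None] + phase[None, :]
    )  # (T, P)
    xy = base_pose[None, :, :] + osc[:, :, None] * direction[None, :, :]
    if noise_sd > 0:
        xy = xy + rng.normal(0.0, noise_sd, xy.shape)
    conf = rng.uniform(0.6, 1.0, (n_frames, n_points, 1))
    coords = np.concatenate([xy, conf], axis=2)
    return KeypointSequence(modality=modality, coords=coords, fps=fps)


def complementary_effects(level: float) -> np.ndarray:
    """Effect matrix planting each indicator's signal in one modality.

    Indicator i gets ``level`` in modality i % 3 (face, voice, gait in
    turn) and 0 elsewhere, so no single modality can decode all ten
    indicators but the fused representation can.
    """
    eff = np.zeros((len(INDICATORS), 3))
    for i in range(len(INDICATORS)):
        eff[i, i % 3] = level
    return eff


def _face_subset(i: int) -> slice:
    return slice(6 * i, 6 * i + 6)


def _subject(spec: CohortSpec, labels: np.ndarray, rng: np.random.Generator):
    """Generate one subject's raw streams from their labels."""
    eff = spec.effects
    # face amplitudes: per-indicator landmark blocks
    face_amp = np.full(68, max(FACE_BASE_AMP + rng.normal(0.0, FACE_AMP_SD), 0.2))
    for i, y in enumerate(labels):
        if y:
            face_amp[_face_subset(i)] += eff[i, 0] * FACE_AMP_SD
    # gait amplitudes: per-indicator joints
    gait_amp = np.full(18, max(GAIT_BASE_AMP + rng.normal(0.0, GAIT_AMP_SD), 0.2))
    for i, y in enumerate(labels):
        if y:
            gait_amp[i] += eff[i, 2] * GAIT_AMP_SD
    # voice: f0 shifts plus a loudness (energy) cue with a distinct
    # per-indicator pattern, so the voice block carries two dimensions
    f0 = F0_BASE + rng.normal(0.0, F0_SD)
    gain = 1.0 + rng.normal(0.0, 0.1)
    for i, y in enumerate(labels):
        if y:
            f0 += eff[i, 1] * F0_SD * (i + 1) / 5.5
            gain += eff[i, 1] * 0.1 * (10 - i) / 5.5
    f0 = float(np.clip(f0, 60.0, 400.0))
    gain = float(np.clip(gain, 0.2, 5.0))

    face_pose = np.stack(
        [rng.uniform(260, 380, 68), rng.uniform(180, 300, 68)], axis=1
    )
    gait_pose = np.stack(
        [rng.uniform(220, 420, 18), rng.uniform(80, 420, 18)], axis=1
    )
    face = generate_keypoint_motion(
        "face", face_pose, face_amp, 0.5, spec.noise_sd["face"],
        spec.face_duration, spec.fps, rng,
    )
    gait = generate_keypoint_motion(
        "gait", gait_pose, gait_amp, 1.2, spec.noise_sd["gait"],
        spec.gait_duration, spec.fps, rng,
    )
    voice = [
        gain
        * synthesize_voice(
            f0, DEFAULT_FORMANTS, spec.voice_duration, spec.sample_rate,
            spec.noise_sd["voice"], rng,
        )
        for _ in range(spec.voice_segments)
    ]
    return face, gait, voice


def generate_cohort_arrays(spec: CohortSpec) -> list[SubjectData]:
    """In-memory cohort: one :class:`SubjectData` per subject."""
    root = np.random.SeedSequence(spec.seed)
    label_rng = np.random.default_rng(root.spawn(1)[0])
    labels = (
        label_rng.uniform(size=(spec.n_subjects, len(INDICATORS)))
        < spec.prevalence[None, :]
    ).astype(int)
    subject_seeds = root.spawn(spec.n_subjects + 1)[1:]
    subjects = []
    for s in range(spec.n_subjects):
        rng = np.random.default_rng(subject_seeds[s])
        face, gait, voice = _subject(spec, labels[s], rng)
        subjects.append(
            SubjectData(
                subject_id=f"s{s:04d}",
                face=face,
                gait=gait,
                voice=voice,
                labels=labels[s],
            )
        )
    return subjects


def generate_cohort(spec: CohortSpec, out_dir) -> Path:
    """Write a cohort to disk: keypoint JSON, WAV, labels CSV, manifest."""
    out = Path(out_dir)
    subj_dir = out / "subjects"
    subj_dir.mkdir(parents=True, exist_ok=True)
    subjects = generate_cohort_arrays(spec)
    rows = ["subject_id," + ",".join(INDICATORS)]
    for sub in subjects:
        write_keypoints_json(sub.face, subj_dir / f"{sub.subject_id}_face.json")
        write_keypoints_json(sub.gait, subj_dir / f"{sub.subject_id}_gait.json")
        for i, wave in enumerate(sub.voice):
            write_wav(
                subj_dir / f"{sub.subject_id}_voice{i}.wav", wave, spec.sample_rate
            )
        rows.append(
            sub.subject_id + "," + ",".join(str(int(v)) for v in sub.labels)
        )
    (out / "labels.csv").write_text("\n".join(rows) + "\n")
    manifest = {
        "format": "mindfuse-cohort-v1",
        "spec": spec.to_dict(),
        "indicators": list(INDICATORS),
        "effect_wiring": {
            "face": "indicator i adds effect*0.3 px amplitude to landmarks 6i..6i+5",
            "gait": "indicator i adds effect*0.4 px amplitude to joint i",
            "voice": "indicator i shifts f0 by effect*5Hz*(i+1)/5.5",
        },
        "subjects": [s.subject_id for s in subjects],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
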