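"""Reading, validation, segmentation and featurization of keypoint streams.

A keypoint stream is an ordered sequence of frames; each frame carries a
fixed number of (x, y, confidence) landmark triplets: 68 for the face, 18
for the body (gait).  The module converts a validated stream into one
scalar time series per landmark — the Euclidean displacement of the point
from its own temporal mean position — which is what the statistics module
consumes.  The raw x/y series are retained on each channel so the
between-axes correlation statistic stays computable.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from mindfuse.errors import (
    KeypointFormatError,
    InsufficientDataError,
    UnrecoverableChannelError,
)

logger = logging.getLogger(__name__)

POINTS_PER_FRAME = {"face": 68, "gait": 18}

#: segment duration in seconds, per modality
SEGMENT_SECONDS = {"face": 30.0, "gait": 8.0}


@dataclass
class KeypointSequence:
    """Per-frame landmark coordinates for one modality.

    ``coords`` has shape (n_frames, points_per_frame, 3) with the last axis
    holding (x, y, confidence).  Pixel coordinates, origin top-left.
    """

    modality: str
    coords: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        if self.modality not in POINTS_PER_FRAME:
            raise ValueError(f"unknown modality {self.modality!r}")
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise KeypointFormatError(
                f"coords must be (frames, points, 3), got {self.coords.shape}"
            )
        expected = POINTS_PER_FRAME[self.modality]
        if self.coords.shape[1] != expected:
            raise KeypointFormatError(
                f"modality {self.modality!r} requires {expected} points per "
                f"frame, got {self.coords.shape[1]}"
            )
        if not self.fps > 0:
            raise ValueError("fps must be positive")
        conf = self.coords[:, :, 2]
        if conf.size and (np.nanmin(conf) < 0 or np.nanmax(conf) > 1):
            raise KeypointFormatError("confidences must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def points_per_frame(self) -> int:
        return self.coords.shape[1]

    @property
    def duration(self) -> float:
        return self.n_frames / self.fps


@dataclass
class ChannelSeries:
    """One scalar time series extracted from a single channel.

    ``channel_id`` is (modality, index).  ``x``/``y`` carry the raw axis
    series for keypoint channels (None for voice channels).
    """

    channel_id: tuple
    values: np.ndarray
    valid_mask: np.ndarray
    x: np.ndarray | None = field(default=None, repr=False)
    y: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if len(self.values) != len(self.valid_mask):
            raise ValueError("values and valid_mask must have equal length")
        if not np.all(np.isfinite(self.values[self.valid_mask])):
            raise ValueError("non-finite values under a true valid_mask")


def _frames_from_json(obj, path):
    """Extract per-frame flat [x, y, c, ...] arrays from parsed JSON."""
    if isinstance(obj, dict) and "frames" in obj:
        obj = obj["frames"]
    if not isinstance(obj, list):
        raise KeypointFormatError(f"{path}: top-level JSON must be a list of frames")
    flat_frames = []
    for i, entry in enumerate(obj):
        if isinstance(entry, dict):
            people = entry.get("people")
            if not people:
                raise KeypointFormatError(f"{path}: frame {i} has no 'people' entry")
            flat = people[0].get("pose_keypoints_2d")
            if flat is None:
                raise KeypointFormatError(
                    f"{path}: frame {i} lacks 'pose_keypoints_2d'"
                )
        elif isinstance(entry, list):
            flat = entry
        else:
            raise KeypointFormatError(f"{path}: frame {i} has unsupported type")
        flat_frames.append(flat)
    return flat_frames


def read_keypoints(path, modality: str, fps: float) -> KeypointSequence:
    """Read a keypoint stream from JSON or long-format CSV.

    JSON: a list with one object per frame, each
    ``{"people": [{"pose_keypoints_2d": [x, y, c, ...]}]}`` (flat triplet
    lists are also accepted).  CSV: long format with columns
    ``frame, point, x, y, confidence``.
    """
    if modality not in POINTS_PER_FRAME:
        raise ValueError(f"unknown modality {modality!r}")
    expected = POINTS_PER_FRAME[modality]
    path = str(path)
    try:
        if path.endswith(".csv"):
            frames = _read_csv_frames(path)
        else:
            with open(path) as fh:
                obj = json.load(fh)
            frames = _frames_from_json(obj, path)
    except OSError as exc:
        raise OSError(f"cannot read keypoint file {path}: {exc}") from exc
    except json.JSONDecodeError as exc:
        raise KeypointFormatError(f"{path}: invalid JSON ({exc})") from exc
    coords = np.empty((len(frames), expected, 3), dtype=float)
    for i, flat in enumerate(frames):
        arr = np.asarray(flat, dtype=float)
        if arr.size != expected * 3:
            raise KeypointFormatError(
                f"{path}: frame {i} has {arr.size // 3} points, "
                f"expected {expected} for modality {modality!r}"
            )
        coords[i] = arr.reshape(expected, 3)
    return KeypointSequence(modality=modality, coords=coords, fps=fps)


def _read_csv_frames(path):
    rows = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise KeypointFormatError(f"{path}: empty CSV")
        cols = {c.lower().strip(): c for c in reader.fieldnames}
        conf_col = cols.get("confidence") or cols.get("conf")
        needed = ("frame", "point", "x", "y")
        if any(c not in cols for c in needed) or conf_col is None:
            raise KeypointFormatError(
                f"{path}: CSV must have columns frame,point,x,y,confidence"
            )
        for row in reader:
            f = int(row[cols["frame"]])
            p = int(row[cols["point"]])
            rows.setdefault(f, {})[p] = (
                float(row[cols["x"]]),
                float(row[cols["y"]]),
                float(row[conf_col]),
            )
    frames = []
    for f in sorted(rows):
        pts = rows[f]
        flat = []
        for p in sorted(pts):
            flat.extend(pts[p])
        frames.append(flat)
    return frames


def write_keypoints_json(seq: KeypointSequence, path) -> None:
    """Serialize in the per-frame ``people``/``pose_keypoints_2d`` dialect."""
    out = [
        {"people": [{"pose_keypoints_2d": [round(v, 6) for v in frame.ravel()]}]}
        for frame in seq.coords
    ]
    with open(path, "w") as fh:
        json.dump(out, fh)


def write_keypoints_csv(seq: KeypointSequence, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame", "point", "x", "y", "confidence"])
        for f in range(seq.n_frames):
            for p in range(seq.points_per_frame):
                x, y, c = seq.coords[f, p]
                writer.writerow([f, p, repr(float(x)), repr(float(y)), repr(float(c))])


def segment_sequence(seq: KeypointSequence) -> list[KeypointSequence]:
    """Split into non-overlapping fixed-duration segments.

    30 s for face, 8 s for gait.  A trailing partial segment at least half
    the target duration is kept; shorter trailers are dropped.  A sequence
    shorter than half a segment yields an empty list with a warning.
    """
    seg_frames = int(round(SEGMENT_SECONDS[seq.modality] * seq.fps))
    half = seg_frames / 2.0
    n = seq.n_frames
    if n < half:
        warnings.warn(
            f"{seq.modality} sequence of {n} frames is shorter than half a "
            f"segment ({seg_frames} frames); no segments produced",
            stacklevel=2,
        )
        return []
    segments = []
    for start in range(0, n, seg_frames):
        chunk = seq.coords[start : start + seg_frames]
        if len(chunk) == seg_frames or len(chunk) >= half:
            segments.append(
                KeypointSequence(modality=seq.modality, coords=chunk, fps=seq.fps)
            )
    return segments


def interpolate_missing(
    seq: KeypointSequence, conf_threshold: float = 0.1
) -> KeypointSequence:
    """Replace low-confidence points by linear interpolation along time.

    Leading/trailing gaps are held at the nearest valid value.  A point
    that is invalid in every frame cannot be recovered and raises
    :class:`UnrecoverableChannelError`.
    """
    if not 0.0 <= conf_threshold <= 1.0:
        raise ValueError("conf_threshold must lie in [0, 1]")
    coords = seq.coords.copy()
    conf = coords[:, :, 2]
    invalid = conf < conf_threshold
    if not invalid.any():
        return KeypointSequence(modality=seq.modality, coords=coords, fps=seq.fps)
    t = np.arange(seq.n_frames, dtype=float)
    for p in range(seq.points_per_frame):
        bad = invalid[:, p]
        if not bad.any():
            continue
        if bad.all():
            raise UnrecoverableChannelError(
                f"point {p} of {seq.modality} sequence is invalid in every frame"
            )
        good = ~bad
        for axis in (0, 1):
            coords[bad, p, axis] = np.interp(t[bad], t[good], coords[good, p, axis])
    return KeypointSequence(modality=seq.modality, coords=coords, fps=seq.fps)


def keypoint_channel_series(seq: KeypointSequence) -> list[ChannelSeries]:
    """One displacement-magnitude series per landmark.

    The value at frame t is the Euclidean distance of the point from its
    own temporal mean position, which makes the series invariant to a
    global translation of the coordinate frame.
    """
    if seq.n_frames < 2:
        raise InsufficientDataError("need at least 2 frames for a time series")
    xy = seq.coords[:, :, :2]
    mean_pos = xy.mean(axis=0)  # (points, 2)
    disp = np.linalg.norm(xy - mean_pos[None, :, :], axis=2)  # (frames, points)
    valid = np.ones(seq.n_frames, dtype=bool)
    return [
        ChannelSeries(
            channel_id=(seq.modality, p),
            values=disp[:, p],
            valid_mask=valid.copy(),
            x=xy[:, p, 0].copy(),
            y=xy[:, p, 1].copy(),
        )
        for p in range(seq.points_per_frame)
    ]
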