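"""Time-domain statistics per channel and per-modality feature matrices.

Nine statistics are supported — arithmetic sum, mean, minimum, maximum,
variance, standard deviation, skewness, kurtosis, and the correlation
coefficient between the two coordinate axes — in that fixed order.  The
default working set is (mean, std, skewness, kurtosis), which gives the
face/voice/gait matrices 68x4, 17x4 and 18x4 shapes and a fused block of
103x4.

Estimator conventions: sample (n-1) variance/std, adjusted Fisher-Pearson
skewness, excess kurtosis; a zero-variance series gets skewness and
kurtosis 0.  The axis correlation is Pearson's r between the raw x and y
series of a keypoint channel; channels without axis data (voice) and
constant axes score 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from mindfuse.errors import InsufficientDataError
from mindfuse.keypoints import ChannelSeries

STAT_ORDER = (
    "sum",
    "mean",
    "min",
    "max",
    "variance",
    "std",
    "skewness",
    "kurtosis",
    "axis_correlation",
)

DEFAULT_STATS = ("mean", "std", "skewness", "kurtosis")

EXPECTED_CHANNELS = {"face": 68, "voice": 17, "gait": 18}


def validate_stat_set(stats) -> tuple:
    """Check membership/uniqueness and return the set in canonical order."""
    stats = tuple(stats)
    if not stats:
        raise ValueError("empty statistic set")
    unknown = [s for s in stats if s not in STAT_ORDER]
    if unknown:
        raise ValueError(f"unknown statistics {unknown}; choose from {STAT_ORDER}")
    if len(set(stats)) != len(stats):
        raise ValueError("duplicate statistics in set")
    return tuple(s for s in STAT_ORDER if s in stats)


@dataclass
class ModalFeatureMatrix:
    """channels x statistics matrix for one modality."""

    modality: str
    matrix: np.ndarray
    channel_ids: list
    stat_names: tuple

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D")
        if self.matrix.shape != (len(self.channel_ids), len(self.stat_names)):
            raise ValueError("matrix shape inconsistent with channel/stat labels")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("feature matrix contains non-finite entries")


def _adj_skewness(centered: np.ndarray, n: int, m2: float) -> float:
    """Adjusted Fisher-Pearson skewness (matches scipy.stats.skew bias=False)."""
    if m2 <= 0 or n < 3:
        return 0.0
    g1 = float(np.mean(centered**3)) / m2**1.5
    return float(np.sqrt(n * (n - 1)) / (n - 2) * g1)


def _excess_kurtosis(centered: np.ndarray, n: int, m2: float) -> float:
    """Bias-corrected excess kurtosis (normal -> 0; scipy bias=False)."""
    if m2 <= 0 or n < 4:
        return 0.0
    g2 = float(np.mean(centered**4)) / m2**2 - 3.0
    return float((n - 1) / ((n - 2) * (n - 3)) * ((n + 1) * g2 + 6.0))


def axis_correlation(x_series, y_series) -> float:
    """Pearson correlation between two axis series; 0 if either is constant."""
    x = np.asarray(x_series, dtype=float)
    y = np.asarray(y_series, dtype=float)
    if len(x) != len(y):
        raise ValueError("axis series must have equal length")
    if len(x) < 2:
        raise InsufficientDataError("need at least 2 points for a correlation")
    sx = x.std()
    sy = y.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = float(np.corrcoef(x, y)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


def channel_statistics(series: ChannelSeries, stats=DEFAULT_STATS) -> np.ndarray:
    """Statistics of the valid part of one channel, in canonical order."""
    stats = validate_stat_set(stats)
    vals = series.values[series.valid_mask]
    if len(vals) < 2:
        raise InsufficientDataError(
            f"channel {series.channel_id} has {len(vals)} valid points (< 2)"
        )
    # center first: higher moments on near-constant series with a large mean
    # otherwise lose all precision to cancellation
    n = len(vals)
    centered = vals - vals.mean()
    m2 = float(np.mean(centered**2))
    var = m2 * n / (n - 1)
    out = []
    for s in stats:
        if s == "sum":
            out.append(float(vals.sum()))
        elif s == "mean":
            out.append(float(vals.mean()))
        elif s == "min":
            out.append(float(vals.min()))
        elif s == "max":
            out.append(float(vals.max()))
        elif s == "variance":
            out.append(var)
        elif s == "std":
            out.append(float(np.sqrt(var)))
        elif s == "skewness":
            out.append(_adj_skewness(centered, n, m2))
        elif s == "kurtosis":
            out.append(_excess_kurtosis(centered, n, m2))
        elif s == "axis_correlation":
            if series.x is None or series.y is None:
                out.append(0.0)
            else:
                out.append(
                    axis_correlation(
                        series.x[series.valid_mask], series.y[series.valid_mask]
                    )
                )
    return np.asarray(out)


def build_modal_feature_matrix(
    channels: list[ChannelSeries], stats=DEFAULT_STATS
) -> ModalFeatureMatrix:
    """Stack per-channel statistics into a channels x |stats| matrix.

    A channel with fewer than two valid points (e.g. a fully unvoiced
    pitch channel) is encoded as a zero row with a warning rather than
    aborting the whole modality.
    """
    if not channels:
        raise ValueError("empty channel list")
    stats = validate_stat_set(stats)
    modalities = {c.channel_id[0] for c in channels}
    if len(modalities) != 1:
        raise ValueError(f"mixed modalities in channel list: {sorted(modalities)}")
    modality = modalities.pop()
    rows = []
    for ch in channels:
        try:
            rows.append(channel_statistics(ch, stats))
        except InsufficientDataError:
            warnings.warn(
                f"channel {ch.channel_id} has too few valid points; row zeroed",
                stacklevel=2,
            )
            rows.append(np.zeros(len(stats)))
    return ModalFeatureMatrix(
        modality=modality,
        matrix=np.vstack(rows),
        channel_ids=[c.channel_id for c in channels],
        stat_names=stats,
    )


def write_matrix_csv(mat: ModalFeatureMatrix, path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["modality", "channel"] + list(mat.stat_names))
        for cid, row in zip(mat.channel_ids, mat.matrix):
            writer.writerow([cid[0], cid[1]] + [repr(float(v)) for v in row])


def read_matrix_csv(path) -> ModalFeatureMatrix:
    import csv

    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        stat_names = tuple(header[2:])
        channel_ids, rows, modality = [], [], None
        for rec in reader:
            modality = rec[0]
            channel_ids.append((rec[0], int(rec[1])))
            rows.append([float(v) for v in rec[2:]])
    if modality is None:
        raise ValueError(f"{path}: no data rows")
    return ModalFeatureMatrix(
        modality=modality,
        matrix=np.asarray(rows),
        channel_ids=channel_ids,
        stat_names=stat_names,
    )
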