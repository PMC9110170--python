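"""Attention-weighted feature-layer fusion of the three modality matrices.

Each modality is summarized by a descriptor (column mean of its feature
matrix, optionally z-scaled with training-set statistics); the query is
the mean of the descriptors.  Similarities (dot, cosine, bilinear or
scaled-dot) pass through a temperature softmax to give one weight per
modality, and each modality block is multiplied by its weight before the
blocks are stacked — face, gait, voice — into the fused 103 x |stats|
matrix.  Row-major flattening yields the classifier input vector (412-D
under the default four statistics).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from mindfuse.stats import ModalFeatureMatrix

SIMILARITY_MODES = ("dot", "cosine", "bilinear", "scaled_dot")

#: fixed stacking order of modality blocks in the fused matrix
BLOCK_ORDER = ("face", "gait", "voice")

#: weight tuple order (w1, w2, w3) = (face, voice, gait)
WEIGHT_ORDER = ("face", "voice", "gait")


@dataclass
class AttentionConfig:
    similarity: str = "cosine"
    temperature: float = 1.0
    bilinear_matrix: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.similarity not in SIMILARITY_MODES:
            raise ValueError(
                f"similarity must be one of {SIMILARITY_MODES}, got "
                f"{self.similarity!r}"
            )
        if not self.temperature > 0:
            raise ValueError("temperature must be positive")
        if self.bilinear_matrix is not None:
            self.bilinear_matrix = np.asarray(self.bilinear_matrix, dtype=float)
            if (
                self.bilinear_matrix.ndim != 2
                or self.bilinear_matrix.shape[0] != self.bilinear_matrix.shape[1]
            ):
                raise ValueError("bilinear_matrix must be square")


@dataclass
class FusedFeature:
    """Weighted concatenation of the modality blocks plus the weights."""

    matrix: np.ndarray
    weights: dict
    block_index: list = field(repr=False)
    stat_names: tuple = ()

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if len(self.block_index) != self.matrix.shape[0]:
            raise ValueError("block_index length must match row count")

    @property
    def weight_tuple(self) -> tuple:
        """(w1, w2, w3) in (face, voice, gait) order."""
        return tuple(self.weights[m] for m in WEIGHT_ORDER)

    def flatten(self) -> np.ndarray:
        """Row-major classifier input vector (412-D under defaults)."""
        return self.matrix.ravel()


@dataclass
class DescriptorScaler:
    """Per-modality, per-column standardization fitted on training data."""

    means: dict
    stds: dict

    @classmethod
    def fit(cls, descriptors_by_modality: dict) -> "DescriptorScaler":
        means, stds = {}, {}
        for mod, desc in descriptors_by_modality.items():
            arr = np.asarray(desc, dtype=float)
            if arr.ndim != 2:
                raise ValueError("descriptors must be (n_samples, n_stats)")
            means[mod] = arr.mean(axis=0)
            s = arr.std(axis=0)
            stds[mod] = np.where(s > 0, s, 1.0)
        return cls(means=means, stds=stds)

    def transform(self, modality: str, descriptor: np.ndarray) -> np.ndarray:
        return (descriptor - self.means[modality]) / self.stds[modality]


def modality_descriptor(
    matrix: ModalFeatureMatrix, scaler: DescriptorScaler | None = None
) -> np.ndarray:
    """Column-wise mean over channels, one value per statistic."""
    if matrix.matrix.size == 0:
        raise ValueError("empty feature matrix")
    desc = matrix.matrix.mean(axis=0)
    if scaler is not None:
        desc = scaler.transform(matrix.modality, desc)
    return desc


def similarity(query, key, config: AttentionConfig) -> float:
    q = np.asarray(query, dtype=float)
    k = np.asarray(key, dtype=float)
    if q.shape != k.shape or q.ndim != 1:
        raise ValueError("query and key must be 1-D vectors of equal length")
    mode = config.similarity
    if mode == "dot":
        return float(q @ k)
    if mode == "cosine":
        nq, nk = np.linalg.norm(q), np.linalg.norm(k)
        if nq == 0 or nk == 0:
            raise ValueError("cosine similarity undefined for zero-norm vectors")
        return float(q @ k / (nq * nk))
    if mode == "bilinear":
        w = config.bilinear_matrix
        if w is None:
            w = np.eye(len(q))
        if w.shape != (len(q), len(q)):
            raise ValueError("bilinear_matrix shape must match vector length")
        return float(k @ w @ q)
    # scaled_dot
    return float(q @ k / np.sqrt(len(q)))


def attention_weights(similarities, temperature: float = 1.0) -> np.ndarray:
    """Numerically stable softmax of similarity scores / temperature."""
    s = np.asarray(similarities, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("similarities must be finite")
    if not temperature > 0:
        raise ValueError("temperature must be positive")
    z = s / temperature
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def fuse(
    face: ModalFeatureMatrix,
    voice: ModalFeatureMatrix,
    gait: ModalFeatureMatrix,
    config: AttentionConfig | None = None,
    scaler: DescriptorScaler | None = None,
    weight_override=None,
) -> FusedFeature:
    """Attention-weighted stack of the three modality matrices.

    ``weight_override`` bypasses the attention computation entirely (e.g.
    (1, 1, 1) reproduces a plain concatenation); it is given in
    (face, voice, gait) order.
    """
    config = config or AttentionConfig()
    mats = {"face": face, "voice": voice, "gait": gait}
    for name, m in mats.items():
        if m.modality != name:
            raise ValueError(f"argument {name} carries modality {m.modality!r}")
    n_cols = {m.matrix.shape[1] for m in mats.values()}
    if len(n_cols) != 1:
        raise ValueError("modality matrices must share the statistic columns")

    if weight_override is not None:
        w = {m: float(v) for m, v in zip(WEIGHT_ORDER, weight_override)}
    else:
        descs = {m: modality_descriptor(mats[m], scaler) for m in WEIGHT_ORDER}
        query = np.mean([descs[m] for m in WEIGHT_ORDER], axis=0)
        sims = [similarity(query, descs[m], config) for m in WEIGHT_ORDER]
        weights = attention_weights(sims, config.temperature)
        w = dict(zip(WEIGHT_ORDER, (float(v) for v in weights)))

    blocks, index = [], []
    for m in BLOCK_ORDER:
        blocks.append(w[m] * mats[m].matrix)
        index.extend([m] * mats[m].matrix.shape[0])
    return FusedFeature(
        matrix=np.vstack(blocks),
        weights=w,
        block_index=index,
        stat_names=face.stat_names,
    )
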