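"""Confusion metrics, cross-validated scoring, and the modality-ablation grid.

The ablation grid evaluates eight conditions — each single modality, each
pair, the plain tri-modal concatenation, and the tri-modal fusion with
attention weights — with stratified k-fold cross-validation per indicator
and pooled out-of-fold predictions.  "Overall" figures are macro-averages
over the ten indicators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC

from mindfuse.classify import INDICATORS
from mindfuse.fusion import (
    BLOCK_ORDER,
    AttentionConfig,
    DescriptorScaler,
    attention_weights,
    similarity,
)

ABLATION_CONDITIONS = (
    "F",
    "V",
    "G",
    "F+V",
    "F+G",
    "V+G",
    "F+V+G",
    "(F+V+G)att",
)

_CONDITION_SPEC = {
    "F": (("face",), False),
    "V": (("voice",), False),
    "G": (("gait",), False),
    "F+V": (("face", "voice"), False),
    "F+G": (("face", "gait"), False),
    "V+G": (("voice", "gait"), False),
    "F+V+G": (("face", "voice", "gait"), False),
    "(F+V+G)att": (("face", "voice", "gait"), True),
}


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def metrics(counts: ConfusionCounts) -> tuple[float, float, float, float]:
    """(accuracy, precision, recall, F1) with zero-denominator conventions.

    precision is 0 when TP+FP = 0, recall is 0 when TP+FN = 0, and F1 is 0
    when precision + recall = 0.
    """
    if counts.total == 0:
        raise ValueError("cannot compute metrics on all-zero counts")
    accuracy = (counts.tp + counts.tn) / counts.total
    precision = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    recall = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return accuracy, precision, recall, f1


@dataclass
class FeatureDataset:
    """Per-subject modality feature blocks plus the 10-way label matrix.

    ``blocks`` maps modality name to an array (n_subjects, channels,
    |stats|); ``labels`` is (n_subjects, 10) binary.
    """

    blocks: dict
    labels: np.ndarray
    stat_names: tuple = ()

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        n = {arr.shape[0] for arr in self.blocks.values()}
        n.add(self.labels.shape[0])
        if len(n) != 1:
            raise ValueError("blocks and labels disagree on subject count")
        if self.labels.ndim != 2 or self.labels.shape[1] != len(INDICATORS):
            raise ValueError(f"labels must be (n, {len(INDICATORS)})")

    @property
    def n_subjects(self) -> int:
        return self.labels.shape[0]


@dataclass
class EvalReport:
    condition: str
    per_indicator: dict
    overall_accuracy: float
    overall_f1: float
    fold_assignments: dict = field(default_factory=dict, repr=False)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.per_indicator).T
        df.index.name = "indicator"
        return df

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "per_indicator": {
                k: {m: float(v) for m, v in d.items()}
                for k, d in self.per_indicator.items()
            },
            "overall_accuracy": float(self.overall_accuracy),
            "overall_f1": float(self.overall_f1),
        }


def condition_features(
    dataset: FeatureDataset,
    modalities,
    attention: bool,
    train_idx,
    attention_config: AttentionConfig | None = None,
    per_sample: bool = True,
) -> np.ndarray:
    """Classifier-ready per-subject feature vectors for one condition.

    Every modality block is flattened and standardized per dimension with
    statistics fitted on the training indices.  With attention enabled,
    the descriptor z-scaler is likewise fitted on the training indices,
    the softmax runs over however many modalities the condition includes
    (two-way for dual conditions), and the weights multiply the
    standardized blocks — weighting before standardization would be
    undone by it.  ``per_sample=False`` replaces each sample's weights by
    the training-set mean weights (the global variant).
    """
    modalities = [m for m in BLOCK_ORDER if m in modalities]
    missing = [m for m in modalities if m not in dataset.blocks]
    if missing:
        raise KeyError(f"dataset lacks modalities {missing}")
    train_idx = np.asarray(train_idx)
    flat = {m: dataset.blocks[m].reshape(dataset.n_subjects, -1) for m in modalities}
    z = {}
    for m in modalities:
        mu = flat[m][train_idx].mean(axis=0)
        sd = flat[m][train_idx].std(axis=0)
        z[m] = (flat[m] - mu) / np.where(sd > 0, sd, 1.0)
    if not attention or len(modalities) == 1:
        return np.concatenate([z[m] for m in modalities], axis=1)
    config = attention_config or AttentionConfig()
    descs = {m: dataset.blocks[m].mean(axis=1) for m in modalities}  # (n, S)
    scaler = DescriptorScaler.fit({m: d[train_idx] for m, d in descs.items()})
    zdescs = np.stack(
        [scaler.transform(m, descs[m]) for m in modalities], axis=0
    )  # (M, n, S)
    n = dataset.n_subjects
    weights = np.empty((n, len(modalities)))
    for i in range(n):
        query = zdescs[:, i].mean(axis=0)
        sims = [
            similarity(query, zdescs[j, i], config) for j in range(len(modalities))
        ]
        weights[i] = attention_weights(sims, config.temperature)
    if not per_sample:
        weights[:] = weights[train_idx].mean(axis=0)[None, :]
    return np.concatenate(
        [weights[:, [j]] * z[m] for j, m in enumerate(modalities)], axis=1
    )


def _splitter(y: np.ndarray, k: int, seed: int, indicator: str):
    n = len(y)
    counts = np.bincount(y, minlength=2)
    if counts.min() == 0:
        raise ValueError(
            f"indicator {indicator!r} has a single class; cannot cross-validate"
        )
    if k >= n:  # leave-one-out
        return KFold(n_splits=n).split(np.zeros(n))
    if counts.min() < k:
        raise ValueError(
            f"indicator {indicator!r}: minority class has {counts.min()} samples, "
            f"fewer than k={k} folds; reduce k or collect more positives"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return skf.split(np.zeros(n), y)


def cross_validate(
    dataset: FeatureDataset,
    condition: str = "(F+V+G)att",
    k: int = 5,
    seed: int = 42,
    C: float = 1.0,
    sigma_rule="scale",
    attention_config: AttentionConfig | None = None,
    per_sample_weights: bool = True,
) -> EvalReport:
    """Pooled out-of-fold metrics per indicator for one condition."""
    if condition not in _CONDITION_SPEC:
        raise ValueError(f"unknown condition {condition!r}")
    if k < 2:
        raise ValueError("k must be at least 2")
    modalities, attention = _CONDITION_SPEC[condition]
    gamma = "scale" if sigma_rule == "scale" else 1.0 / (2.0 * float(sigma_rule) ** 2)
    per_indicator = {}
    fold_assignments = {}
    for j, name in enumerate(INDICATORS):
        y = dataset.labels[:, j]
        preds = np.zeros_like(y)
        assignment = np.full(len(y), -1)
        for fold, (train_idx, test_idx) in enumerate(
            _splitter(y, k, seed, name)
        ):
            X = condition_features(
                dataset,
                modalities,
                attention,
                train_idx,
                attention_config,
                per_sample=per_sample_weights,
            )
            clf = SVC(kernel="rbf", C=C, gamma=gamma)
            clf.fit(X[train_idx], y[train_idx])
            preds[test_idx] = clf.predict(X[test_idx])
            assignment[test_idx] = fold
        counts = ConfusionCounts(
            tp=int(np.sum((preds == 1) & (y == 1))),
            tn=int(np.sum((preds == 0) & (y == 0))),
            fp=int(np.sum((preds == 1) & (y == 0))),
            fn=int(np.sum((preds == 0) & (y == 1))),
        )
        acc, prec, rec, f1 = metrics(counts)
        per_indicator[name] = {
            "accuracy": acc,
            "precision": prec,
            "recall": rec,
            "f1": f1,
        }
        fold_assignments[name] = assignment
    overall_acc = float(np.mean([d["accuracy"] for d in per_indicator.values()]))
    overall_f1 = float(np.mean([d["f1"] for d in per_indicator.values()]))
    return EvalReport(
        condition=condition,
        per_indicator=per_indicator,
        overall_accuracy=overall_acc,
        overall_f1=overall_f1,
        fold_assignments=fold_assignments,
    )


def ablation_grid(dataset: FeatureDataset, seed: int = 42, **cv_kwargs) -> list:
    """Evaluate all eight ablation conditions on one dataset.

    Conditions needing a modality absent from the dataset are skipped with
    a warning.
    """
    reports = []
    for condition in ABLATION_CONDITIONS:
        modalities, _ = _CONDITION_SPEC[condition]
        if any(m not in dataset.blocks for m in modalities):
            warnings.warn(
                f"condition {condition} skipped: missing modality", stacklevel=2
            )
            continue
        reports.append(
            cross_validate(dataset, condition=condition, seed=seed, **cv_kwargs)
        )
    return reports
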