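"""Binary-relevance bank of ten Gaussian-kernel SVMs, one per indicator.

Each indicator is an independent binary problem (positive = screening
positive for that indicator).  Features are standardized with statistics
fitted on the training set; the kernel width follows the "scale"
heuristic sigma^2 = d * Var(X) / 2, i.e. kernel coefficient
gamma = 1 / (d * Var(X)).  The soft-margin penalty defaults to C = 1.
A polynomial ``degree`` setting is accepted for config compatibility but
has no effect under a Gaussian kernel.
"""

from __future__ import annotations

from dataclasses import dataclass

import joblib
import numpy as np
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

INDICATORS = (
    "somatization",
    "obsessive_compulsive",
    "interpersonal_sensitivity",
    "depression",
    "anxiety",
    "hostility",
    "dreadness",
    "crankiness",
    "psychopathy",
    "other",
)


def gaussian_kernel(x, z, sigma: float) -> float:
    """exp(-||x - z||^2 / (2 sigma^2)); symmetric, in (0, 1]."""
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    if x.shape != z.shape:
        raise ValueError("x and z must have equal shape")
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    d2 = float(np.sum((x - z) ** 2))
    return float(np.exp(-d2 / (2.0 * sigma**2)))


@dataclass
class ClassifierBank:
    classifiers: dict
    scaler: StandardScaler
    C: float
    gamma: object
    n_features: int

    def __post_init__(self) -> None:
        if set(self.classifiers) != set(INDICATORS):
            raise ValueError("bank must hold exactly one classifier per indicator")

    @property
    def sigma(self) -> dict:
        """Effective Gaussian width per indicator (sigma^2 = 1 / (2 gamma))."""
        out = {}
        for name, clf in self.classifiers.items():
            out[name] = float(np.sqrt(1.0 / (2.0 * clf._gamma)))
        return out


def _as_matrix(features) -> np.ndarray:
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.ndim != 2:
        raise ValueError("features must be (n_samples, n_features)")
    return X


def train_bank(
    features,
    labels,
    C: float = 1.0,
    sigma_rule="scale",
    degree: int = 3,
    class_weight=None,
) -> ClassifierBank:
    """Fit the ten-indicator SVM bank.

    ``sigma_rule`` is "scale" (the d*Var heuristic) or an explicit numeric
    sigma.  ``degree`` is accepted and ignored (it only applies to
    polynomial kernels).  Raises if some indicator has fewer than two
    samples of either class, naming the indicator.
    """
    del degree  # recorded for config fidelity; meaningless for a Gaussian kernel
    X = _as_matrix(features)
    y = np.asarray(labels, dtype=int)
    if y.ndim != 2 or y.shape[1] != len(INDICATORS):
        raise ValueError(f"labels must be (n_samples, {len(INDICATORS)})")
    if y.shape[0] != X.shape[0]:
        raise ValueError("features and labels disagree on sample count")
    if not C > 0:
        raise ValueError("C must be positive")
    if sigma_rule == "scale":
        gamma = "scale"
    else:
        sigma = float(sigma_rule)
        if not sigma > 0:
            raise ValueError("explicit sigma must be positive")
        gamma = 1.0 / (2.0 * sigma**2)

    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    classifiers = {}
    for j, name in enumerate(INDICATORS):
        counts = np.bincount(y[:, j], minlength=2)
        if counts.min() < 2:
            raise ValueError(
                f"indicator {name!r} has {counts[0]} negative / {counts[1]} "
                "positive samples; need at least 2 of each class"
            )
        clf = SVC(kernel="rbf", C=C, gamma=gamma, class_weight=class_weight)
        clf.fit(Xs, y[:, j])
        classifiers[name] = clf
    return ClassifierBank(
        classifiers=classifiers,
        scaler=scaler,
        C=C,
        gamma=gamma,
        n_features=X.shape[1],
    )


def predict(bank: ClassifierBank, features, return_scores: bool = False):
    """Ten binary decisions per sample; optionally the decision scores."""
    X = _as_matrix(features)
    if X.shape[1] != bank.n_features:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match the trained "
            f"dimension {bank.n_features}"
        )
    Xs = bank.scaler.transform(X)
    labels = np.column_stack(
        [bank.classifiers[name].predict(Xs) for name in INDICATORS]
    ).astype(int)
    if not return_scores:
        return labels
    scores = np.column_stack(
        [bank.classifiers[name].decision_function(Xs) for name in INDICATORS]
    )
    return labels, scores


def save_bank(bank: ClassifierBank, path) -> None:
    joblib.dump(bank, path)


def load_bank(path) -> ClassifierBank:
    bank = joblib.load(path)
    if not isinstance(bank, ClassifierBank):
        raise ValueError(f"{path} does not contain a ClassifierBank")
    return bank
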