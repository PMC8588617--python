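"""Binary-classification evaluation: confusion metrics, K-fold CV, t CIs.

Metrics follow the standard confusion-matrix definitions

    recall      = TP / (TP + FN)          precision = TP / (TP + FP)
    specificity = TN / (TN + FP)          accuracy  = (TP + TN) / n
    F1          = 2 TP / (2 TP + FP + FN)

with 0/0 reported as an explicit ``UNDEFINED`` marker rather than 0 or an
exception.  The confidence interval for K-fold CV accuracy is the
symmetric t interval mu +/- c * sqrt(sigma2) where sigma2 is the
variance-of-the-mean estimator sum_k (acc_k - mu)^2 / (K (K - 1)) and c
the two-sided t quantile with K - 1 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np
from scipy import stats
from sklearn.model_selection import KFold, StratifiedKFold

from . import network as net

#: marker for metrics whose defining ratio is 0/0
UNDEFINED = float("nan")


def is_undefined(value: float) -> bool:
    return np.isnan(value)


@dataclass(frozen=True)
class ConfusionMatrix:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "TN", "FP", "FN"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a nonnegative integer, got {v}")
        if self.n < 1:
            raise ValueError("confusion matrix must count at least one sample")

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.TP + other.TP, self.TN + other.TN,
                               self.FP + other.FP, self.FN + other.FN)

    def swapped(self) -> "ConfusionMatrix":
        """The same predictions under the opposite positive-class convention."""
        return ConfusionMatrix(TP=self.TN, TN=self.TP, FP=self.FN, FN=self.FP)


@dataclass(frozen=True)
class MetricsReport:
    recall: float
    precision: float
    specificity: float
    accuracy: float
    f1: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("recall", "precision", "specificity", "accuracy", "f1")}


@dataclass(frozen=True)
class CIResult:
    mean: float
    variance: float
    quantile: float
    confidence: float
    lo: float
    hi: float

    @property
    def half_width(self) -> float:
        return (self.hi - self.lo) / 2


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Count joint outcomes of true vs predicted binary labels."""
    yt = np.asarray(y_true).astype(int)
    yp = np.asarray(y_pred).astype(int)
    if yt.shape != yp.shape or yt.ndim != 1:
        raise ValueError("y_true and y_pred must be 1-D and the same length")
    if yt.size < 1:
        raise ValueError("need at least one sample")
    return ConfusionMatrix(
        TP=int(np.sum((yt == 1) & (yp == 1))),
        TN=int(np.sum((yt == 0) & (yp == 0))),
        FP=int(np.sum((yt == 0) & (yp == 1))),
        FN=int(np.sum((yt == 1) & (yp == 0))),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den else UNDEFINED


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    return MetricsReport(
        recall=_ratio(cm.TP, cm.TP + cm.FN),
        precision=_ratio(cm.TP, cm.TP + cm.FP),
        specificity=_ratio(cm.TN, cm.TN + cm.FP),
        accuracy=_ratio(cm.TP + cm.TN, cm.n),
        f1=_ratio(2 * cm.TP, 2 * cm.TP + cm.FP + cm.FN),
    )


def kfold_split(n: int, K: int, seed: int, labels=None) -> list[np.ndarray]:
    """Shuffled K-fold partition of range(n); stratified if labels given.

    Fold sizes differ by at most one and the same seed reproduces the same
    folds exactly.
    """
    if K < 2:
        raise net.ConfigError("K must be >= 2")
    if K > n:
        raise net.ConfigError(f"cannot split {n} samples into {K} folds")
    if labels is not None:
        splitter = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
        return [test for _, test in splitter.split(np.zeros(n), np.asarray(labels))]
    splitter = KFold(n_splits=K, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(np.zeros(n))]


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    config: "net.NetworkConfig",
    K: int = 5,
    stratified: bool = True,
    threshold: float = 0.5,
) -> tuple[list[float], ConfusionMatrix, MetricsReport]:
    """K-fold CV of the classifier: per-fold accuracies + pooled metrics.

    Each fold trains a fresh model (seeded from config.seed + fold index)
    on the other K-1 folds and scores the held-out fold; pooled predictions
    over all folds give the confusion matrix and metrics.
    """
    y = np.asarray(y).astype(int)
    folds = kfold_split(len(y), K, seed=config.seed, labels=y if stratified else None)
    accuracies: list[float] = []
    pooled: ConfusionMatrix | None = None
    for k, test_idx in enumerate(folds):
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[test_idx] = False
        y_tr = y[train_mask]
        if len(np.unique(y_tr)) < 2:
            raise net.TrainingError(
                "a training split contains a single class; enable stratification"
            )
        fold_cfg = _dc_replace(config, seed=config.seed + 101 * (k + 1))
        model = net.build_aninet(fold_cfg)
        net.train(model, X[train_mask], y_tr, fold_cfg)
        _, pred = net.predict(model, X[test_idx], threshold=threshold)
        cm = confusion(y[test_idx], pred)
        accuracies.append(metrics(cm).accuracy)
        pooled = cm if pooled is None else pooled + cm
    return accuracies, pooled, metrics(pooled)


def t_confidence_interval(fold_accuracies, alpha: float = 0.05) -> CIResult:
    """Symmetric t-distribution CI for the mean of K fold accuracies."""
    acc = np.asarray(fold_accuracies, dtype=float)
    K = acc.size
    if K < 2:
        raise net.ConfigError("need at least 2 folds for a confidence interval")
    mu = float(acc.mean())
    sigma2 = float(np.sum((acc - mu) ** 2) / (K * (K - 1)))
    c = float(stats.t.ppf(1 - alpha / 2, df=K - 1))
    half = c * np.sqrt(sigma2)
    return CIResult(mean=mu, variance=sigma2, quantile=c, confidence=1 - alpha,
                    lo=mu - half, hi=mu + half)
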