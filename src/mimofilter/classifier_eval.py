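"""Accuracy assessment of a selected feature set.

A Gaussian naive Bayes classifier (class-conditional univariate normals,
empirical priors, log-space posteriors) is scored by the four criteria
used for prognostic signatures: AUC, 1 - RMSE, SAR and the F score.
Pairwise classifier comparisons use an exact-binomial McNemar test on
discordant errors together with a Wilcoxon signed-rank test on paired
squared errors, with Holm's step-down adjustment across comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import logsumexp

__all__ = [
    "ProbPrediction",
    "MetricsReport",
    "nb_fit_predict",
    "auc",
    "rmse",
    "sar",
    "f_score",
    "metrics_report",
    "compare_classifiers",
    "holm_adjust",
]

_VAR_FLOOR = 1e-9


@dataclass
class ProbPrediction:
    """Posterior probability of the positive class per test sample, with
    the hard label at threshold 0.5."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if np.any(~np.isfinite(self.probs)) or np.any(
            (self.probs < 0) | (self.probs > 1)
        ):
            raise ValueError("probabilities must be finite and in [0, 1]")

    @property
    def labels(self) -> np.ndarray:
        return (self.probs >= 0.5).astype(np.int8)


@dataclass(frozen=True)
class MetricsReport:
    auc: float
    one_minus_rmse: float
    sar: float
    f: float
    n_test: int


def nb_fit_predict(train_X, train_y, test_X) -> ProbPrediction:
    """Gaussian naive Bayes: fit on the training set, return positive-class
    posteriors on the test set.

    Per class and feature, a univariate normal with the class mean and
    (floored) population variance; class priors are empirical frequencies;
    posteriors are computed in log space for numerical stability.
    """
    train_X = np.atleast_2d(np.asarray(train_X, dtype=float))
    test_X = np.atleast_2d(np.asarray(test_X, dtype=float))
    y = np.asarray(train_y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("training target must have exactly two classes")
    log_joint = np.empty((test_X.shape[0], 2))
    for idx, c in enumerate(classes):
        rows = train_X[y == c]
        mu = rows.mean(axis=0)
        var = np.maximum(rows.var(axis=0), _VAR_FLOOR)
        log_lik = -0.5 * (
            np.log(2 * np.pi * var) + (test_X - mu) ** 2 / var
        ).sum(axis=1)
        log_joint[:, idx] = np.log(rows.shape[0] / y.size) + log_lik
    log_post = log_joint - logsumexp(log_joint, axis=1, keepdims=True)
    return ProbPrediction(probs=np.exp(log_post[:, 1]))


def _check_two_classes(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("labels must contain exactly two classes")
    return (labels == classes.max()).astype(int)


def auc(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic.

    Ties among scores count one half, the standard convention.
    """
    y = _check_two_classes(labels)
    ranks = stats.rankdata(np.asarray(scores, dtype=float))
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def rmse(probs, labels) -> float:
    """Root mean squared error of probabilities against 0/1 labels."""
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=float)
    return float(np.sqrt(np.mean((p - y) ** 2)))


def sar(accuracy: float, auc_value: float, rmse_value: float) -> float:
    """Composite SAR score: mean of accuracy, AUC and 1 - RMSE."""
    return (accuracy + auc_value + (1.0 - rmse_value)) / 3.0


def f_score(pred_labels, labels) -> float:
    """F1 for the positive (high-risk) class; 0 when precision + recall = 0."""
    pred = np.asarray(pred_labels).astype(int)
    y = np.asarray(labels).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)


def metrics_report(prediction: ProbPrediction, labels) -> MetricsReport:
    """All four criteria for one prediction/label pair."""
    y = np.asarray(labels).astype(int)
    hard = prediction.labels
    acc = float(np.mean(hard == y))
    a = auc(prediction.probs, y)
    r = rmse(prediction.probs, y)
    return MetricsReport(
        auc=a,
        one_minus_rmse=1.0 - r,
        sar=sar(acc, a, r),
        f=f_score(hard, y),
        n_test=y.size,
    )


def compare_classifiers(errA, errB, sq_errA, sq_errB) -> tuple[float, float]:
    """Paired comparison of two classifiers on the same test samples.

    Returns (mcnemar_p, wilcoxon_p): an exact-binomial McNemar test on the
    discordant 0/1 error counts, and a Wilcoxon signed-rank test on the
    paired squared errors with zero differences dropped. Identical error
    patterns give p = 1 by convention (no evidence of a difference).
    """
    a = np.asarray(errA).astype(bool)
    b = np.asarray(errB).astype(bool)
    if a.shape != b.shape:
        raise ValueError("error vectors must have equal length")
    n01 = int(np.sum(a & ~b))
    n10 = int(np.sum(~a & b))
    if n01 + n10 == 0:
        mcnemar_p = 1.0
    else:
        mcnemar_p = float(
            stats.binomtest(n01, n01 + n10, 0.5, alternative="two-sided").pvalue
        )
    diffs = np.asarray(sq_errA, dtype=float) - np.asarray(sq_errB, dtype=float)
    diffs = diffs[diffs != 0.0]
    if diffs.size == 0:
        wilcoxon_p = 1.0
    else:
        wilcoxon_p = float(stats.wilcoxon(diffs, mode="auto").pvalue)
    return mcnemar_p, wilcoxon_p


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values.

    Order-preserving, never below the raw p-values, capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_max = 0.0
    for rank, idx in enumerate(order):
        running_max = max(running_max, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running_max)
    return adjusted
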