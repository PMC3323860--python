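"""Multi-dataset validation protocols.

Two cross-study designs evaluate the causal filter the way prognostic
gene signatures are evaluated across cohorts:

* ``holdout_protocol`` — repeated stratified half/half splits of every
  study; feature selection uses Fisher-z pooled correlations from the
  training halves only, and a Gaussian naive Bayes is trained on the
  pooled training halves and scored on the pooled test halves.
* ``lodo_protocol`` — leave-one-dataset-out: features are selected on the
  pooled remaining studies, never on the held-out one; repeated half/half
  splits *within* the held-out study then measure generalization, and
  per-dataset win/loss counts compare each causal setting (lambda > 0)
  against the plain ranking (lambda = 0), requiring both the McNemar and
  the Wilcoxon test to be significant after Holm adjustment.

Survival outcomes are reduced to a binary risk class at a fixed horizon
(default 5 years): events at or before the horizon are high risk,
follow-up beyond the horizon is low risk, and samples censored before the
horizon are excluded as uninformative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import PooledGaussianStats
from .causal_filter import FilterConfig, forward_rank_from_stats
from .classifier_eval import (
    compare_classifiers,
    holm_adjust,
    metrics_report,
    nb_fit_predict,
)
from .data import Dataset, FeatureMatrix, TargetSet
from .infotheory import CLAMP_EPS

__all__ = [
    "StudyCollection",
    "ProtocolResult",
    "binarize_survival",
    "pooled_correlation",
    "holdout_protocol",
    "lodo_protocol",
]

_METRIC_COLS = ["auc", "one_minus_rmse", "sar", "f"]


def binarize_survival(time, event, horizon: float = 5.0):
    """Binary risk class at a follow-up horizon.

    Returns ``(labels, included)``: label 1 (high risk) where the event
    occurred at or before the horizon; label 0 (low risk) where follow-up
    exceeds the horizon; samples censored before the horizon carry no
    information about the class and are masked out (label set to 0,
    ``included`` False).
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event).astype(int)
    if t.shape != e.shape:
        raise ValueError("time and event must have equal length")
    if np.any(t < 0):
        raise ValueError("negative survival time")
    high = (e == 1) & (t <= horizon)
    low = t > horizon
    labels = np.where(high, 1, 0).astype(np.int8)
    included = high | low
    return labels, included


def pooled_correlation(per_study) -> float:
    """Meta-analytic pooled correlation: Fisher-z transform each study
    coefficient, average with inverse-variance weights (n - 3), and
    back-transform. Studies with n < 4 are dropped with a warning."""
    zs, ws = [], []
    for rho, n in per_study:
        if n < 4:
            warnings.warn(f"study with n={n} < 4 dropped from pooling")
            continue
        clipped = float(np.clip(rho, -1.0 + CLAMP_EPS, 1.0 - CLAMP_EPS))
        zs.append(np.arctanh(clipped))
        ws.append(n - 3.0)
    if not ws:
        raise ValueError("no study with n >= 4 to pool")
    return float(np.tanh(np.average(zs, weights=ws)))


@dataclass
class StudyCollection:
    """Several datasets sharing a feature identifier space.

    ``align()`` restricts every study to the identifier intersection, in
    the column order of the first study, logging dropped features.
    """

    studies: list[Dataset]
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.studies:
            raise ValueError("empty study collection")
        if not self.names:
            self.names = [s.name or f"study{i}" for i, s in enumerate(self.studies)]
        if len(self.names) != len(self.studies):
            raise ValueError("names/studies length mismatch")
        m0 = self.studies[0].targets.n_targets
        if any(s.targets.n_targets != m0 for s in self.studies):
            raise ValueError("all studies must have the same number of targets")

    def __len__(self) -> int:
        return len(self.studies)

    def align(self) -> "StudyCollection":
        common = set(self.studies[0].features.feature_ids)
        for s in self.studies[1:]:
            common &= set(s.features.feature_ids)
        if not common:
            raise ValueError("no shared feature identifiers across studies")
        ordered = [f for f in self.studies[0].features.feature_ids if f in common]
        aligned = []
        for s in self.studies:
            dropped = len(s.features.feature_ids) - len(ordered)
            if dropped:
                warnings.warn(f"{s.name}: {dropped} features outside the intersection")
            idx = [s.features.feature_ids.index(f) for f in ordered]
            aligned.append(
                Dataset(
                    features=s.features.subset(idx),
                    targets=s.targets,
                    truth=s.truth,
                    name=s.name,
                )
            )
        return StudyCollection(studies=aligned, names=list(self.names))


@dataclass
class ProtocolResult:
    """Per-repetition metrics plus, for leave-one-dataset-out, win/loss
    counts of each lambda > 0 setting against lambda = 0."""

    per_rep: pd.DataFrame
    win_loss: pd.DataFrame | None = None

    def aggregate(self) -> pd.DataFrame:
        return (
            self.per_rep.groupby(["v", "lam"], as_index=False)[_METRIC_COLS]
            .mean()
            .sort_values(["v", "lam"], ignore_index=True)
        )


def _rows(features: FeatureMatrix, idx: np.ndarray) -> FeatureMatrix:
    return FeatureMatrix(
        values=features.values[idx],
        feature_ids=list(features.feature_ids),
        constant=features.constant,
    )


def _valid_half(targets: TargetSet, train_idx, test_idx) -> bool:
    for y in targets.all_targets:
        tr, te = y[train_idx], y[test_idx]
        # conditional correlations need >= 3 per class on the training side
        if min(np.sum(tr == 0), np.sum(tr == 1)) < 3:
            return False
        if np.unique(te).size < 2:
            return False
    return True


def stratified_half_split(targets: TargetSet, rng: np.random.Generator):
    """Half/half split stratified by the primary class, re-drawn until all
    targets are usable in both halves (at most 100 attempts)."""
    y = targets.primary
    n = y.size
    for _ in range(100):
        train_parts = []
        for c in (0, 1):
            idx = np.flatnonzero(y == c)
            rng.shuffle(idx)
            train_parts.append(idx[: idx.size // 2 + (idx.size % 2 and rng.integers(2))])
        train_idx = np.sort(np.concatenate(train_parts))
        test_idx = np.setdiff1d(np.arange(n), train_idx)
        if _valid_half(targets, train_idx, test_idx):
            return train_idx, test_idx
    raise RuntimeError("could not stratify a valid half/half split in 100 attempts")


def _rank_feature_sets(stats, v_list, lambda_list):
    """Forward-rank once per lambda to max(v); return {(v, lam): indices}."""
    v_max = max(v_list)
    sets = {}
    for lam in lambda_list:
        cfg = FilterConfig(lambda_=lam, v=v_max)
        ranking = forward_rank_from_stats(stats, cfg)
        for v in v_list:
            sets[(v, lam)] = ranking.order[:v]
    return sets


def holdout_protocol(
    studies: StudyCollection,
    v_list,
    lambda_list,
    reps: int = 100,
    seed: int = 0,
) -> ProtocolResult:
    """Repeated stratified half/half validation across all studies."""
    studies = studies.align()
    v_list = sorted(set(int(v) for v in v_list))
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(reps):
        halves = [
            stratified_half_split(s.targets, rng) for s in studies.studies
        ]
        train_data = [
            (_rows(s.features, tr), s.targets.subset(tr))
            for s, (tr, _) in zip(studies.studies, halves)
        ]
        stats = PooledGaussianStats(train_data)
        feature_sets = _rank_feature_sets(stats, v_list, lambda_list)
        train_X_full = np.vstack([X.values for X, _ in train_data])
        train_y = np.concatenate([Y.primary for _, Y in train_data])
        test_X_full = np.vstack(
            [s.features.values[te] for s, (_, te) in zip(studies.studies, halves)]
        )
        test_y = np.concatenate(
            [s.targets.primary[te] for s, (_, te) in zip(studies.studies, halves)]
        )
        for (v, lam), cols in feature_sets.items():
            pred = nb_fit_predict(train_X_full[:, cols], train_y, test_X_full[:, cols])
            rep_metrics = metrics_report(pred, test_y)
            rows.append(
                {
                    "dataset": "pooled",
                    "rep": rep,
                    "v": v,
                    "lam": lam,
                    "auc": rep_metrics.auc,
                    "one_minus_rmse": rep_metrics.one_minus_rmse,
                    "sar": rep_metrics.sar,
                    "f": rep_metrics.f,
                    "n_test": rep_metrics.n_test,
                }
            )
    return ProtocolResult(per_rep=pd.DataFrame(rows))


def lodo_protocol(
    studies: StudyCollection,
    v_list,
    lambda_list,
    reps: int = 100,
    seed: int = 0,
) -> ProtocolResult:
    """Leave-one-dataset-out validation.

    Selection never sees the held-out cohort; generalization is measured
    by repeated half/half splits inside it. Win/loss counts per (v,
    lambda > 0) give the number of datasets on which the causal filter is
    significantly better/worse than plain ranking by BOTH the exact
    McNemar test and the Wilcoxon test on squared errors, each Holm-
    adjusted across datasets at level 0.05.
    """
    if len(studies) < 2:
        raise ValueError("leave-one-dataset-out requires at least 2 studies")
    studies = studies.align()
    v_list = sorted(set(int(v) for v in v_list))
    lambda_list = list(lambda_list)
    if 0.0 not in lambda_list:
        raise ValueError("lambda_list must include 0.0 (the ranking baseline)")
    rng = np.random.default_rng(seed)
    rows = []
    # per (dataset, v, lam): concatenated per-sample errors over repetitions
    errors: dict[tuple[str, int, float], list[np.ndarray]] = {}
    sq_errors: dict[tuple[str, int, float], list[np.ndarray]] = {}
    for held_idx, held in enumerate(studies.studies):
        others = [
            (s.features, s.targets)
            for i, s in enumerate(studies.studies)
            if i != held_idx
        ]
        stats = PooledGaussianStats(others)
        feature_sets = _rank_feature_sets(stats, v_list, lambda_list)
        name = studies.names[held_idx]
        for rep in range(reps):
            tr, te = stratified_half_split(held.targets, rng)
            y_tr = held.targets.primary[tr]
            y_te = held.targets.primary[te]
            for (v, lam), cols in feature_sets.items():
                pred = nb_fit_predict(
                    held.features.values[np.ix_(tr, cols)],
                    y_tr,
                    held.features.values[np.ix_(te, cols)],
                )
                rep_metrics = metrics_report(pred, y_te)
                rows.append(
                    {
                        "dataset": name,
                        "rep": rep,
                        "v": v,
                        "lam": lam,
                        "auc": rep_metrics.auc,
                        "one_minus_rmse": rep_metrics.one_minus_rmse,
                        "sar": rep_metrics.sar,
                        "f": rep_metrics.f,
                        "n_test": rep_metrics.n_test,
                    }
                )
                key = (name, v, lam)
                errors.setdefault(key, []).append(pred.labels != y_te)
                sq_errors.setdefault(key, []).append((pred.probs - y_te) ** 2)

    wl_rows = []
    for v in v_list:
        for lam in lambda_list:
            if lam == 0.0:
                continue
            mc_p, wx_p, better = [], [], []
            for name in studies.names:
                err_c = np.concatenate(errors[(name, v, lam)])
                err_r = np.concatenate(errors[(name, v, 0.0)])
                sq_c = np.concatenate(sq_errors[(name, v, lam)])
                sq_r = np.concatenate(sq_errors[(name, v, 0.0)])
                p1, p2 = compare_classifiers(err_c, err_r, sq_c, sq_r)
                mc_p.append(p1)
                wx_p.append(p2)
                better.append(int(err_c.sum()) < int(err_r.sum()))
            mc_adj = holm_adjust(mc_p)
            wx_adj = holm_adjust(wx_p)
            sig = (mc_adj < 0.05) & (wx_adj < 0.05)
            wins = int(np.sum(sig & np.asarray(better)))
            losses = int(np.sum(sig & ~np.asarray(better)))
            wl_rows.append({"v": v, "lam": lam, "wins": wins, "losses": losses})
    return ProtocolResult(
        per_rep=pd.DataFrame(rows), win_loss=pd.DataFrame(wl_rows)
    )
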