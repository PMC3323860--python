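"""Correlation providers feeding the forward-selection filter.

The filter only ever needs three families of sufficient statistics, all of
them Pearson correlations under the Gaussian MI approximation:

* the point-biserial correlation of every feature with the primary target
  (relevance),
* rows of the feature-feature correlation matrix (marginal term of the
  interaction), and
* rows of the within-class feature-feature correlation matrix for each
  target and class, with empirical class frequencies (conditional term).

``EmpiricalGaussianStats`` estimates these from a single dataset.
``PooledGaussianStats`` combines several datasets through Fisher-z
inverse-variance pooling (weight n - 3 per study), the standard
meta-analytic estimator of a common correlation, so that selection can
draw on all training cohorts at once. Rows are computed lazily: a full
feature-by-feature matrix is never materialized, which keeps memory
linear in the number of selection steps.
"""

from __future__ import annotations

import numpy as np

from .data import FeatureMatrix, TargetSet
from .infotheory import CLAMP_EPS

__all__ = ["EmpiricalGaussianStats", "PooledGaussianStats", "gaussian_mi_vec"]


def gaussian_mi_vec(rho: np.ndarray) -> np.ndarray:
    """Vectorized -1/2 ln(1 - rho^2) with the usual clamping."""
    r = np.minimum(np.abs(rho), 1.0 - CLAMP_EPS)
    return -0.5 * np.log1p(-r * r)


def _unit_columns(values: np.ndarray) -> np.ndarray:
    """Center columns and scale to unit L2 norm so dot products are
    correlations; zero-variance columns become all-zero (correlation 0)."""
    centered = values - values.mean(axis=0)
    norms = np.sqrt((centered**2).sum(axis=0))
    norms[norms == 0.0] = 1.0
    return centered / norms


def _clip(rho: np.ndarray) -> np.ndarray:
    return np.clip(rho, -1.0, 1.0)


class EmpiricalGaussianStats:
    """Sufficient statistics of one dataset."""

    def __init__(self, X: FeatureMatrix, Y: TargetSet) -> None:
        if X.n_samples != Y.n_samples:
            raise ValueError("features and targets disagree on sample count")
        if X.n_samples < 2:
            raise ValueError("need at least 2 samples")
        self.feature_ids = list(X.feature_ids)
        self.n_features = X.n_features
        self.n_targets = Y.n_targets
        self._units = _unit_columns(X.values)
        # per target: list over classes of (fraction, unit-column submatrix)
        self._class_units: list[list[tuple[float, np.ndarray]]] = []
        for y in Y.all_targets:
            per_class = []
            for c in (0, 1):
                mask = y == c
                n_c = int(mask.sum())
                if n_c < 3:
                    raise ValueError(
                        f"target class {c} has {n_c} observations (< 3); "
                        "within-class correlation undefined"
                    )
                per_class.append((n_c / y.size, _unit_columns(X.values[mask])))
            self._class_units.append(per_class)
        y_unit = _unit_columns(Y.primary.astype(float)[:, None])[:, 0]
        self._relevance_rho = _clip(y_unit @ self._units)

    def relevance_rho(self) -> np.ndarray:
        return self._relevance_rho

    def marginal_rho_row(self, i: int) -> np.ndarray:
        u = self._units[:, i]
        return _clip(u @ self._units)

    def class_fractions(self, j: int) -> np.ndarray:
        return np.array([frac for frac, _ in self._class_units[j]])

    def conditional_rho_rows(self, i: int, j: int) -> np.ndarray:
        """Within-class correlation rows for target j, shape (2, n_features)."""
        rows = [_clip(units[:, i] @ units) for _, units in self._class_units[j]]
        return np.stack(rows)


def _pool_fisher(rhos: list[np.ndarray], weights: list[float]) -> np.ndarray:
    """Inverse-variance pooling on the Fisher z scale, back-transformed."""
    w = np.asarray(weights, dtype=float)
    if np.all(w <= 0):
        w = np.ones_like(w)  # degenerate tiny studies: fall back to equal weights
    w = np.maximum(w, 0.0)
    z = np.zeros_like(rhos[0])
    for rho, wk in zip(rhos, w):
        clipped = np.clip(rho, -1.0 + CLAMP_EPS, 1.0 - CLAMP_EPS)
        z = z + wk * np.arctanh(clipped)
    return np.tanh(z / w.sum())


class PooledGaussianStats:
    """Fisher-z pooled statistics over several aligned datasets.

    All datasets must share the same feature identifiers in the same
    order (align them upstream). Correlations are pooled with weights
    n - 3 (the inverse asymptotic variance of Fisher's z); class
    frequencies are pooled as overall counts.
    """

    def __init__(self, datasets: list[tuple[FeatureMatrix, TargetSet]]) -> None:
        if not datasets:
            raise ValueError("need at least one dataset")
        ids0 = list(datasets[0][0].feature_ids)
        m0 = datasets[0][1].n_targets
        for X, Y in datasets[1:]:
            if list(X.feature_ids) != ids0:
                raise ValueError("datasets must share an identical feature space")
            if Y.n_targets != m0:
                raise ValueError("datasets must share the target structure")
        self.feature_ids = ids0
        self.n_features = len(ids0)
        self.n_targets = m0
        self._studies = [EmpiricalGaussianStats(X, Y) for X, Y in datasets]
        self._marg_w = [float(X.n_samples - 3) for X, _ in datasets]
        # within-class sample counts per target/class, per study
        self._class_n = [
            [
                [int(round(frac * Y.n_samples)) for frac, _ in s._class_units[j]]
                for j in range(m0)
            ]
            for s, (X, Y) in zip(self._studies, datasets)
        ]
        self._relevance_rho = _pool_fisher(
            [s.relevance_rho() for s in self._studies], self._marg_w
        )

    def relevance_rho(self) -> np.ndarray:
        return self._relevance_rho

    def marginal_rho_row(self, i: int) -> np.ndarray:
        return _pool_fisher(
            [s.marginal_rho_row(i) for s in self._studies], self._marg_w
        )

    def class_fractions(self, j: int) -> np.ndarray:
        counts = np.zeros(2)
        for study_counts in self._class_n:
            counts += np.asarray(study_counts[j], dtype=float)
        return counts / counts.sum()

    def conditional_rho_rows(self, i: int, j: int) -> np.ndarray:
        rows = []
        for c in (0, 1):
            per_study = [s.conditional_rho_rows(i, j)[c] for s in self._studies]
            weights = [float(ns[j][c] - 3) for ns in self._class_n]
            rows.append(_pool_fisher(per_study, weights))
        return np.stack(rows)
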