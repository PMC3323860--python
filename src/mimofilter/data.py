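"""Core in-memory containers: standardized feature matrices and target sets."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["FeatureMatrix", "TargetSet", "Dataset", "standardize_columns"]


def standardize_columns(raw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center and scale columns to mean 0, sd 1 (population sd).

    Returns the standardized matrix and a boolean mask of constant columns,
    which are left as all-zeros rather than dividing by zero.
    """
    raw = np.asarray(raw, dtype=float)
    mean = raw.mean(axis=0)
    sd = raw.std(axis=0)
    constant = sd == 0.0
    safe_sd = np.where(constant, 1.0, sd)
    out = (raw - mean) / safe_sd
    out[:, constant] = 0.0
    return out, constant


@dataclass
class FeatureMatrix:
    """Samples-by-features matrix with columns standardized to mean 0, sd 1.

    Constant columns cannot be standardized; they are stored as zeros and
    flagged in ``constant`` so downstream correlation code treats them as
    carrying no information.
    """

    values: np.ndarray
    feature_ids: list[str]
    constant: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D (samples x features)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")
        if len(self.feature_ids) != self.values.shape[1]:
            raise ValueError("feature_ids length must match the number of columns")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature identifiers")
        if self.constant is None:
            self.constant = np.zeros(self.values.shape[1], dtype=bool)

    @classmethod
    def from_raw(cls, raw, feature_ids=None) -> "FeatureMatrix":
        """Standardize a raw matrix; constant columns are flagged, not fatal."""
        raw = np.asarray(raw, dtype=float)
        if feature_ids is None:
            feature_ids = [f"f{j}" for j in range(raw.shape[1])]
        values, constant = standardize_columns(raw)
        if constant.any():
            names = [feature_ids[j] for j in np.flatnonzero(constant)]
            warnings.warn(f"constant feature columns standardized to zero: {names}")
        return cls(values=values, feature_ids=list(feature_ids), constant=constant)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, indices) -> "FeatureMatrix":
        indices = np.asarray(indices, dtype=int)
        return FeatureMatrix(
            values=self.values[:, indices],
            feature_ids=[self.feature_ids[j] for j in indices],
            constant=self.constant[indices],
        )


def _validate_binary(y, name: str, n_expected: int | None) -> np.ndarray:
    arr = np.asarray(y)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    classes = np.unique(arr)
    if classes.size != 2:
        raise ValueError(f"{name} must have exactly two classes, found {classes.size}")
    if n_expected is not None and arr.size != n_expected:
        raise ValueError(f"{name} length {arr.size} != {n_expected}")
    return (arr == classes.max()).astype(np.int8)


@dataclass
class TargetSet:
    """One primary binary target plus zero or more secondary binary targets.

    Relevance is always measured against the primary; all targets
    (primary included) participate in the structural causal score.
    """

    primary: np.ndarray
    secondaries: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.primary = _validate_binary(self.primary, "primary target", None)
        self.secondaries = [
            _validate_binary(s, f"secondary target {i}", self.primary.size)
            for i, s in enumerate(self.secondaries)
        ]

    @property
    def n_samples(self) -> int:
        return self.primary.size

    @property
    def all_targets(self) -> list[np.ndarray]:
        return [self.primary, *self.secondaries]

    @property
    def n_targets(self) -> int:
        return 1 + len(self.secondaries)

    def subset(self, rows) -> "TargetSet":
        rows = np.asarray(rows)
        return TargetSet(
            primary=self.primary[rows],
            secondaries=[s[rows] for s in self.secondaries],
        )


@dataclass
class Dataset:
    """A feature matrix paired with its targets and, when simulated, the
    ground-truth causal role of every feature."""

    features: FeatureMatrix
    targets: TargetSet
    truth: dict[str, str] | None = None
    name: str = "dataset"

    def __post_init__(self) -> None:
        if self.features.n_samples != self.targets.n_samples:
            raise ValueError("features and targets disagree on sample count")
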