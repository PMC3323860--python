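"""Mutual information under the Gaussian approximation.

All estimators reduce mutual information to Pearson correlation through
the closed form I = -1/2 log(1 - rho^2), which is exact for bivariate
Gaussian variables and used here as an approximation everywhere else.
Mixed continuous/binary terms use the point-biserial correlation (the
Pearson correlation with the 0/1 class encoding); class-conditional
terms average the within-class Gaussian MI with empirical class
frequencies as weights.

Values are in nats. Correlations are clamped to ``|rho| <= 1 - CLAMP_EPS``
so collinear inputs yield a large finite MI instead of infinity.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "CLAMP_EPS",
    "pearson_correlation",
    "gaussian_mi",
    "mi_cc",
    "mi_cd",
    "conditional_mi_cc",
    "interaction_information",
]

#: correlation magnitudes are clamped below 1 by this margin to keep MI finite
CLAMP_EPS = 1e-12


def _as_vector(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if arr.size < 2:
        raise ValueError(f"{name} must have length >= 2, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def pearson_correlation(x1, x2) -> float:
    """Sample Pearson correlation coefficient of two equal-length vectors.

    A zero-variance (constant) input yields 0.0 with a warning: a constant
    carries no information, and aborting on constant probes would make
    genome-scale matrices unusable.
    """
    a = _as_vector(x1, "x1")
    b = _as_vector(x2, "x2")
    if a.size != b.size:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    a = a - a.mean()
    b = b - b.mean()
    sa = np.sqrt(a @ a)
    sb = np.sqrt(b @ b)
    if sa == 0.0 or sb == 0.0:
        warnings.warn(
            "zero-variance input to pearson_correlation; returning 0.0",
            stacklevel=2,
        )
        return 0.0
    r = float((a @ b) / (sa * sb))
    # numerical round-off can push |r| marginally above 1
    return min(1.0, max(-1.0, r))


def gaussian_mi(rho: float) -> float:
    """MI of a bivariate Gaussian with correlation ``rho``: -1/2 ln(1 - rho^2).

    ``rho`` is clamped to ``|rho| <= 1 - CLAMP_EPS`` so the result stays
    finite on collinear inputs. Even in ``rho`` and strictly increasing in
    ``|rho|``.
    """
    r = float(rho)
    if not np.isfinite(r):
        raise ValueError("rho must be finite")
    if abs(r) > 1.0 + 1e-9:
        raise ValueError(f"|rho| > 1: {r}")
    r = min(abs(r), 1.0 - CLAMP_EPS)
    return -0.5 * np.log1p(-r * r)


def mi_cc(x1, x2) -> float:
    """MI between two continuous vectors via the Gaussian approximation."""
    return gaussian_mi(pearson_correlation(x1, x2))


def _check_binary(y) -> np.ndarray:
    arr = np.asarray(y)
    classes = np.unique(arr)
    if classes.size < 2:
        raise ValueError("target has one class")
    if classes.size > 2:
        raise ValueError(f"target must be binary, found {classes.size} classes")
    return arr


def mi_cd(x, y) -> float:
    """MI between a continuous vector and a binary class vector.

    The class is encoded 0/1 and the point-biserial correlation is plugged
    into the Gaussian closed form. This keeps every term of the filter on
    the same correlation scale; it is an approximation (a 0/1 variable is
    not Gaussian) and is documented as such.
    """
    arr = _check_binary(y)
    encoded = (arr == np.max(arr)).astype(float)
    return gaussian_mi(pearson_correlation(x, encoded))


def conditional_mi_cc(x1, x2, y) -> float:
    """Class-conditional MI: sum_c p(c) * gaussian_mi(rho_c).

    ``rho_c`` is the within-class Pearson correlation and ``p(c)`` the
    empirical class frequency. Requires at least 3 observations per class
    so the within-class correlation is defined.
    """
    arr = _check_binary(y)
    a = _as_vector(x1, "x1")
    b = _as_vector(x2, "x2")
    if a.size != b.size or a.size != arr.size:
        raise ValueError("x1, x2 and y must share a common length")
    total = 0.0
    for c in np.unique(arr):
        mask = arr == c
        n_c = int(mask.sum())
        if n_c < 3:
            raise ValueError(f"class {c!r} has {n_c} observations (< 3)")
        total += (n_c / arr.size) * gaussian_mi(pearson_correlation(a[mask], b[mask]))
    return total


def interaction_information(x1, x2, y) -> float:
    """Three-way interaction information I(x1; x2) - I(x1; x2 | y).

    Negative values indicate synergy (collider patterns: conditioning on
    a common effect induces dependence between its parents); positive
    values indicate redundancy (common cause or chain). Symmetric in
    ``x1`` and ``x2``.
    """
    return mi_cc(x1, x2) - conditional_mi_cc(x1, x2, y)
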