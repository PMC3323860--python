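"""Cause-prioritization metrics over simulation trials.

Measures how well a full ranking prioritizes the known direct causes of
the simulated disease node: the mean 1-based position of the causes, and
the fraction of the top-k slots they occupy. Trial-level values are
aggregated with a normal-approximation confidence interval (default 90%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .causal_filter import RankingResult

__all__ = ["TrialSummary", "average_cause_rank", "top_k_cause_rate", "summarize_trials"]


@dataclass(frozen=True)
class TrialSummary:
    mean: float
    ci_half_width: float
    n_trials: int
    level: float


def average_cause_rank(ranking: RankingResult, cause_ids: set[str]) -> float:
    """Mean 1-based ranking position of the cause features.

    Requires a full ranking (every cause must appear)."""
    if not cause_ids:
        raise ValueError("cause_ids is empty")
    return float(np.mean([ranking.rank_of(c) for c in cause_ids]))


def top_k_cause_rate(
    ranking: RankingResult, cause_ids: set[str], k: int = 5, strict: bool = False
) -> float:
    """Fraction of the first k positions occupied by cause features.

    With ``strict=True`` returns 1.0 only when *all* causes sit in the
    top k (the all-or-nothing reading), else 0.0.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(ranking.order):
        raise ValueError("k exceeds the ranking length")
    top = set(ranking.ordered_ids[:k])
    if strict:
        return 1.0 if cause_ids <= top else 0.0
    return len(top & cause_ids) / k


def summarize_trials(values, level: float = 0.90) -> TrialSummary:
    """Mean with a z-interval: mean +/- z_{(1+level)/2} * sd / sqrt(T)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 trial values")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2)
    half = float(z * arr.std(ddof=1) / np.sqrt(arr.size))
    return TrialSummary(
        mean=float(arr.mean()), ci_half_width=half, n_trials=arr.size, level=level
    )
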