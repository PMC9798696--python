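"""One-sided two-sample Kolmogorov-Smirnov tests for SST selection.

The presence SST sample is compared against the pooled pseudo-absence SST
sample in each direction separately:

* direction "warmer": H0 is that the presence CDF is not below the
  absence CDF; D = max(F_absence - F_presence). Rejection means the
  presence distribution is shifted toward higher SST.
* direction "colder": the mirror image, D = max(F_presence - F_absence).

D is floored at 0 and the p-value is the asymptotic one-sided two-sample
formula p = exp(-2 D^2 m n / (m + n)), capped at 1. ECDFs are evaluated
right-continuously on the pooled values, so ties are deterministic.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "KSResult",
    "SelectionOutcome",
    "GROUPINGS",
    "ks_one_sided",
    "ks_one_sided_from_sorted",
    "classify_selection",
    "aggregate_samples",
    "bonferroni_alpha",
]

GROUPINGS = ("all", "monthly", "bimonthly", "quarterly", "semiannual", "yearly")


@dataclass(frozen=True)
class KSResult:
    direction: str  # "warmer" or "colder"
    D: float
    p_value: float
    n_presence: int
    n_absence: int


@dataclass(frozen=True)
class SelectionOutcome:
    """Joint classification of the two one-sided tests at level alpha."""

    outcome: str  # "warmer", "colder", "both", or "none"
    alpha: float
    warm: KSResult | None = None
    cold: KSResult | None = None


def _one_sided_D(presence_sorted: np.ndarray, absence_sorted: np.ndarray,
                 direction: str) -> float:
    m, n = presence_sorted.size, absence_sorted.size
    pooled = np.concatenate([presence_sorted, absence_sorted])
    f_p = np.searchsorted(presence_sorted, pooled, side="right") / m
    f_a = np.searchsorted(absence_sorted, pooled, side="right") / n
    if direction == "warmer":
        d = np.max(f_a - f_p)
    else:
        d = np.max(f_p - f_a)
    return float(max(d, 0.0))


def ks_one_sided_from_sorted(presence_sorted, absence_sorted, direction) -> KSResult:
    """One-sided KS on pre-sorted arrays (hot path for the power harness)."""
    if direction not in ("warmer", "colder"):
        raise ValueError("direction must be 'warmer' or 'colder'")
    m, n = presence_sorted.size, absence_sorted.size
    if m == 0 or n == 0:
        raise ValueError("both samples must be non-empty")
    d = _one_sided_D(presence_sorted, absence_sorted, direction)
    p = min(1.0, float(np.exp(-2.0 * d * d * m * n / (m + n))))
    return KSResult(direction, d, p, m, n)


def ks_one_sided(presence_sst, absence_sst, direction: str) -> KSResult:
    """One-sided two-sample KS test of SST selection.

    ``direction="warmer"`` asks whether presences are shifted to higher
    SST than pseudo-absences; ``"colder"`` the opposite. See module
    docstring for the statistic and p-value.
    """
    p_arr = np.asarray(presence_sst, dtype=float)
    a_arr = np.asarray(absence_sst, dtype=float)
    if p_arr.size == 0 or a_arr.size == 0:
        raise ValueError("both samples must be non-empty")
    if not (np.all(np.isfinite(p_arr)) and np.all(np.isfinite(a_arr))):
        raise ValueError("samples must be finite")
    return ks_one_sided_from_sorted(np.sort(p_arr), np.sort(a_arr), direction)


def classify_selection(p_warm: float, p_cold: float, alpha: float = 0.05,
                       warm: KSResult | None = None,
                       cold: KSResult | None = None) -> SelectionOutcome:
    """Classify the pair of one-sided tests at significance level alpha.

    alpha may be 0 or 1 for degenerate threshold sweeps (nothing /
    everything significant); ordinary use is 0 < alpha < 1.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    sig_w, sig_c = p_warm <= alpha, p_cold <= alpha
    if sig_w and sig_c:
        outcome = "both"
    elif sig_w:
        outcome = "warmer"
    elif sig_c:
        outcome = "colder"
    else:
        outcome = "none"
    return SelectionOutcome(outcome, alpha, warm, cold)


def bonferroni_alpha(alpha: float, k_tests: int) -> float:
    """Bonferroni-adjusted per-test significance level alpha / k."""
    if k_tests < 1:
        raise ValueError("k_tests must be >= 1")
    return alpha / k_tests


def _group_key(date: _dt.date, grouping: str):
    if grouping == "all":
        return "all"
    month = date.month
    if grouping == "monthly":
        return month
    if grouping == "bimonthly":
        return (month - 1) // 2 + 1
    if grouping == "quarterly":
        return (month - 1) // 3 + 1
    if grouping == "semiannual":
        return (month - 1) // 6 + 1
    if grouping == "yearly":
        return "all"
    raise ValueError(f"grouping must be one of {GROUPINGS}, got {grouping!r}")


def aggregate_samples(
    per_track_samples: Iterable[tuple[Sequence, Sequence[float]]],
    grouping: str = "all",
) -> dict:
    """Pool dated SST samples across tracks by calendar period of year.

    ``per_track_samples`` yields (dates, values) pairs per track.
    Grouping is by period-of-year (e.g. "quarterly" pools January-March
    across all years into one group) so that seasonally varying selection
    can be examined; "yearly"/"all" pool everything. Returns a dict
    group-key -> pooled numpy array; empty groups are absent.
    """
    pools: dict = {}
    for dates, values in per_track_samples:
        for d, v in zip(dates, values):
            if isinstance(d, np.datetime64):
                d = d.astype("datetime64[D]").astype(_dt.date)
            pools.setdefault(_group_key(d, grouping), []).append(float(v))
    return {k: np.asarray(v) for k, v in pools.items()}
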