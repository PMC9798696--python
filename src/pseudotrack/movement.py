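"""Per-calendar-month step-length and turning-angle statistics of tracks.

These empirical distributions are the basis of all environmentally naive
null models: Brownian steps use the monthly log-space moments of step
length, CRW draws steps and turning angles from the monthly empirical
marginals, and JCRW resamples observed (turning angle, step length) pairs
jointly, preserving the long-step/small-turn correlation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .geo import (
    Track,
    TrackSet,
    great_circle_km_arr,
    initial_bearing_arr,
    wrap_angle_deg,
)

logger = logging.getLogger(__name__)

__all__ = [
    "StepAngleSample",
    "MonthlyMovementStats",
    "NoDataError",
    "extract_steps_angles",
    "fit_monthly_stats",
]


class NoDataError(ValueError):
    """Requested a month with no movement samples and no fallback."""


@dataclass(frozen=True)
class StepAngleSample:
    """One step of a track: length, turn relative to the previous step.

    ``turning_deg`` is NaN for a track's first step (no previous bearing).
    ``month`` is the calendar month of the fix the step arrives at.
    """

    step_km: float
    turning_deg: float
    month: int
    dt_days: int


def extract_steps_angles(track: Track) -> list[StepAngleSample]:
    """Steps and signed turning angles of one track.

    Step i is the great-circle distance fix(i-1) -> fix(i); the turning
    angle is the wrapped difference between consecutive step bearings
    (positive = rightward). Zero-length steps are dropped: their bearing,
    hence the adjacent turning angles, is undefined.
    """
    lats, lons = track.lats(), track.lons()
    dates = track.dates
    steps = great_circle_km_arr(lats[:-1], lons[:-1], lats[1:], lons[1:])
    dts = np.array([(dates[i + 1] - dates[i]).days for i in range(len(dates) - 1)])
    months = np.array([dates[i + 1].month for i in range(len(dates) - 1)])
    bearings = initial_bearing_arr(lats[:-1], lons[:-1], lats[1:], lons[1:])

    out: list[StepAngleSample] = []
    prev_bearing = None
    for i in range(steps.size):
        if steps[i] <= 0:
            continue
        turn = float("nan") if prev_bearing is None else float(
            wrap_angle_deg(bearings[i] - prev_bearing)
        )
        out.append(StepAngleSample(float(steps[i]), turn, int(months[i]), int(dts[i])))
        prev_bearing = bearings[i]
    return out


@dataclass
class MonthlyMovementStats:
    """Pooled per-month movement distributions.

    For each month with data: log-space moments of step length (for the
    Brownian sampler), the raw empirical step and turning-angle arrays
    (for CRW), and matched (angle, step) pairs (for JCRW). Months without
    data fall back to the all-months pool, with a warning, when sampling.
    """

    steps: dict[int, np.ndarray] = field(default_factory=dict)
    angles: dict[int, np.ndarray] = field(default_factory=dict)
    joint: dict[int, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    allow_fallback: bool = True

    # -- derived ----------------------------------------------------------
    def months(self) -> list[int]:
        return sorted(self.steps)

    def n_samples(self, month: int) -> int:
        return int(self.steps.get(month, np.empty(0)).size)

    def log_mean(self, month: int) -> float:
        return float(np.mean(np.log(self._month_steps(month))))

    def log_sd(self, month: int) -> float:
        return float(np.std(np.log(self._month_steps(month)), ddof=0))

    def all_steps(self) -> np.ndarray:
        return np.concatenate([self.steps[m] for m in self.months()])

    def _pool(self, d: dict, month: int):
        if month in d and (np.size(d[month][0]) if isinstance(d[month], tuple) else d[month].size):
            return d[month]
        if not self.allow_fallback:
            raise NoDataError(f"no movement samples for month {month}")
        logger.warning("no samples for month %d; falling back to the all-month pool", month)
        vals = [d[m] for m in sorted(d)]
        if not vals:
            raise NoDataError("movement statistics are empty")
        if isinstance(vals[0], tuple):
            return (np.concatenate([v[0] for v in vals]),
                    np.concatenate([v[1] for v in vals]))
        return np.concatenate(vals)

    def _month_steps(self, month: int) -> np.ndarray:
        return self._pool(self.steps, month)

    def _month_angles(self, month: int) -> np.ndarray:
        return self._pool(self.angles, month)

    def _month_joint(self, month: int):
        return self._pool(self.joint, month)

    # -- samplers ----------------------------------------------------------
    def sample_step(self, month: int, rng: np.random.Generator, size=None):
        """Uniform draw(s) from the month's empirical step lengths (km)."""
        return rng.choice(self._month_steps(month), size=size)

    def sample_angle(self, month: int, rng: np.random.Generator, size=None):
        """Uniform draw(s) from the month's empirical turning angles (deg)."""
        return rng.choice(self._month_angles(month), size=size)

    def sample_joint(self, month: int, rng: np.random.Generator, size=None):
        """Joint (turning angle deg, step km) draw(s) by pair resampling."""
        ang, stp = self._month_joint(month)
        idx = rng.integers(0, ang.size, size=size)
        return ang[idx], stp[idx]

    # -- serialisation -----------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "allow_fallback": self.allow_fallback,
            "months": {
                str(m): {
                    "steps": self.steps[m].tolist(),
                    "angles": self.angles[m].tolist(),
                    "joint_angles": self.joint[m][0].tolist(),
                    "joint_steps": self.joint[m][1].tolist(),
                    "log_mean": self.log_mean(m),
                    "log_sd": self.log_sd(m),
                    "n": self.n_samples(m),
                }
                for m in self.months()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "MonthlyMovementStats":
        with open(path) as fh:
            payload = json.load(fh)
        obj = cls(allow_fallback=bool(payload.get("allow_fallback", True)))
        for m_str, d in payload["months"].items():
            m = int(m_str)
            obj.steps[m] = np.asarray(d["steps"], dtype=float)
            obj.angles[m] = np.asarray(d["angles"], dtype=float)
            obj.joint[m] = (np.asarray(d["joint_angles"], dtype=float),
                            np.asarray(d["joint_steps"], dtype=float))
        return obj


def fit_monthly_stats(
    trackset: TrackSet | list[Track],
    max_dt_days: int = 1,
    allow_fallback: bool = True,
) -> MonthlyMovementStats:
    """Pool step/angle samples across tracks by calendar month.

    Steps whose gap to the previous fix exceeds ``max_dt_days`` are
    excluded (a multi-day displacement is not a daily step); pass a larger
    value to keep them. Log moments are computed on ln(step_km).
    """
    by_month_steps: dict[int, list] = {}
    by_month_angles: dict[int, list] = {}
    by_month_joint: dict[int, list] = {}
    for track in trackset:
        for s in extract_steps_angles(track):
            if s.dt_days > max_dt_days:
                continue
            by_month_steps.setdefault(s.month, []).append(s.step_km)
            if not np.isnan(s.turning_deg):
                by_month_angles.setdefault(s.month, []).append(s.turning_deg)
                by_month_joint.setdefault(s.month, []).append((s.turning_deg, s.step_km))
    if not by_month_steps:
        raise NoDataError("no usable steps in the track set")
    stats = MonthlyMovementStats(allow_fallback=allow_fallback)
    for m, vals in by_month_steps.items():
        stats.steps[m] = np.asarray(vals, dtype=float)
        ang = by_month_angles.get(m, [])
        stats.angles[m] = np.asarray(ang, dtype=float)
        pairs = by_month_joint.get(m, [])
        if pairs:
            a, st = zip(*pairs)
            stats.joint[m] = (np.asarray(a, dtype=float), np.asarray(st, dtype=float))
        else:
            stats.joint[m] = (np.empty(0), np.empty(0))
    return stats
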