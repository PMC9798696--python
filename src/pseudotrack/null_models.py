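"""Environmentally naive null movement models with monthly restarts.

Four simulators generate pseudo-absence tracks from an observed (or
synthetic presence) track:

* **brownian** — isotropic: uniform bearing, step length lognormal with the
  month's log-space moments (sampling in log space keeps steps positive,
  consistent with moments being fit on log-transformed data; a truncated
  linear-Gaussian alternative is available via ``brownian_space``).
* **levy** — isotropic with truncated power-law steps p(l) ~ l^(-mu) on
  [l_min, l_max], sampled by exact inverse-CDF.
* **crw** — correlated random walk: turning angle and step length drawn
  independently from the month's empirical marginals; heading accumulates.
* **jcrw** — joint CRW: (turning angle, step length) resampled as observed
  pairs, preserving their correlation.

Every simulated track is re-anchored to the observed animal position at
the start of each calendar month ("monthly restart"), which keeps the
pseudo-absences inside the region the animal actually used; segments are
independent (headings do not carry across restarts).

Gaps in the source track: Brownian/Levy rescale the step by
sqrt(dt_new/dt_ref) (diffusive scaling); CRW/JCRW instead walk through the
missing days with daily draws and only the fix dates are recorded.
"""

from __future__ import annotations

import datetime as _dt
import zlib
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from .geo import GeoPosition, TimedFix, Track, destination_arr, initial_bearing_arr
from .movement import MonthlyMovementStats

__all__ = [
    "MODELS",
    "LevyParams",
    "NullModelConfig",
    "PseudoTrackSet",
    "levy_pdf",
    "levy_inverse_cdf",
    "default_levy_params",
    "rescale_step",
    "simulate_segment",
    "generate_pseudo_tracks",
]

MODELS = ("brownian", "levy", "crw", "jcrw")
_MODEL_CODE = {m: i for i, m in enumerate(MODELS)}


@dataclass(frozen=True)
class LevyParams:
    """Truncated power-law step distribution: exponent and support (km).

    Truncation at l_max gives finite variance, so mu only needs to be
    positive (the classical 1 < mu <= 3 applies to the untruncated law).
    """

    mu: float = 2.0
    l_min: float = 0.001  # 1 m
    l_max: float = 150.0

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be > 0")
        if self.l_min <= 0 or self.l_max <= self.l_min:
            raise ValueError("need 0 < l_min < l_max")


def default_levy_params(stats: MonthlyMovementStats, mu: float = 2.0) -> LevyParams:
    """Levy defaults anchored to the data: l_max = 3x the 99.5th pct step."""
    l_max = 3.0 * float(np.percentile(stats.all_steps(), 99.5))
    return LevyParams(mu=mu, l_min=0.001, l_max=l_max)


def levy_pdf(l, params: LevyParams):
    """Truncated power-law density (per km); 0 outside [l_min, l_max]."""
    l = np.asarray(l, dtype=float)
    if params.mu == 1.0:
        norm = 1.0 / (np.log(params.l_max) - np.log(params.l_min))
    else:
        norm = (1.0 - params.mu) / (
            params.l_max ** (1.0 - params.mu) - params.l_min ** (1.0 - params.mu)
        )
    with np.errstate(divide="ignore"):
        dens = norm * l ** (-params.mu)
    out = np.where((l >= params.l_min) & (l <= params.l_max), dens, 0.0)
    return float(out) if out.ndim == 0 else out


def levy_inverse_cdf(u, params: LevyParams):
    """Quantile function of the truncated power law (exact inversion)."""
    u = np.asarray(u, dtype=float)
    if np.any((u < 0) | (u > 1)):
        raise ValueError("u must lie in [0, 1]")
    if params.mu == 1.0:
        out = params.l_min * (params.l_max / params.l_min) ** u
    else:
        e = 1.0 - params.mu
        out = (params.l_min**e + u * (params.l_max**e - params.l_min**e)) ** (1.0 / e)
    return float(out) if out.ndim == 0 else out


def rescale_step(step, dt_new: float, dt_ref: float = 1.0):
    """Diffusive step rescaling: step * sqrt(dt_new / dt_ref)."""
    if dt_new <= 0 or dt_ref <= 0:
        raise ValueError("dt values must be > 0")
    return step * np.sqrt(dt_new / dt_ref)


@dataclass
class NullModelConfig:
    """Configuration of a pseudo-absence cohort."""

    model: str = "brownian"
    n_replicates: int = 100
    seed: int = 0
    levy: Optional[LevyParams] = None
    brownian_space: str = "log"  # "log" (lognormal) or "linear" (truncated Gaussian)

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.brownian_space not in ("log", "linear"):
            raise ValueError("brownian_space must be 'log' or 'linear'")


@dataclass
class PseudoTrackSet:
    """Replicate pseudo-absence tracks, date-aligned with their source."""

    source_track_id: str
    model: str
    dates: list[_dt.date]
    lats: np.ndarray  # (n_replicates, n_fixes)
    lons: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def n_replicates(self) -> int:
        return self.lats.shape[0]

    def track(self, r: int) -> Track:
        fixes = [
            TimedFix(d, GeoPosition(float(self.lats[r, i]), float(self.lons[r, i])))
            for i, d in enumerate(self.dates)
        ]
        return Track(f"{self.source_track_id}:{self.model}:{r}", fixes)

    def tracks(self) -> Iterator[Track]:
        for r in range(self.n_replicates):
            yield self.track(r)


# ---------------------------------------------------------------------------
# segment simulation
# ---------------------------------------------------------------------------

def _uniform_bearing(rng, n):
    return rng.uniform(0.0, 360.0, size=n)


def _draw_brownian_steps(stats, month, rng, n, space):
    mu, sd = stats.log_mean(month), stats.log_sd(month)
    if space == "log":
        return np.exp(rng.normal(mu, sd, size=n))
    mean = float(np.mean(stats._month_steps(month)))
    std = float(np.std(stats._month_steps(month)))
    draws = rng.normal(mean, std, size=n)
    while np.any(draws <= 0):  # truncate at zero by redraw
        bad = draws <= 0
        draws[bad] = rng.normal(mean, std, size=int(bad.sum()))
    return draws


def simulate_segment_many(
    model: str,
    start: GeoPosition,
    dates: list[_dt.date],
    stats: MonthlyMovementStats,
    rng: np.random.Generator,
    n_replicates: int = 1,
    levy: Optional[LevyParams] = None,
    brownian_space: str = "log",
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate ``n_replicates`` independent segments from one anchor.

    Returns (lats, lons) arrays of shape (n_replicates, len(dates)); the
    first column equals the anchor exactly. Vectorised across replicates;
    replicate r corresponds to row r of every per-step draw, so a cohort
    is reproducible from its generator regardless of how it is consumed.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    n_fix = len(dates)
    lats = np.empty((n_replicates, n_fix))
    lons = np.empty((n_replicates, n_fix))
    lats[:, 0] = start.lat
    lons[:, 0] = start.lon
    if n_fix == 1:
        return lats, lons

    if model in ("brownian", "levy"):
        if model == "levy" and levy is None:
            raise ValueError("levy model requires LevyParams")
        cur_lat, cur_lon = lats[:, 0].copy(), lons[:, 0].copy()
        for i in range(1, n_fix):
            dt = (dates[i] - dates[i - 1]).days
            month = dates[i].month
            bearing = _uniform_bearing(rng, n_replicates)
            if model == "brownian":
                step = _draw_brownian_steps(stats, month, rng, n_replicates, brownian_space)
            else:
                step = levy_inverse_cdf(rng.uniform(0.0, 1.0, size=n_replicates), levy)
            step = rescale_step(step, dt, 1.0)
            cur_lat, cur_lon = destination_arr(cur_lat, cur_lon, bearing, step)
            lats[:, i], lons[:, i] = cur_lat, cur_lon
        return lats, lons

    # crw / jcrw: walk every calendar day, record only the fix dates
    all_days = [dates[0] + _dt.timedelta(days=k)
                for k in range((dates[-1] - dates[0]).days + 1)]
    record = {d: i for i, d in enumerate(dates)}
    heading = _uniform_bearing(rng, n_replicates)
    cur_lat, cur_lon = lats[:, 0].copy(), lons[:, 0].copy()
    first = True
    for day in all_days[1:]:
        month = day.month
        if model == "crw":
            turn = stats.sample_angle(month, rng, size=n_replicates)
            step = stats.sample_step(month, rng, size=n_replicates)
        else:
            turn, step = stats.sample_joint(month, rng, size=n_replicates)
        if first:
            # the first step has no previous bearing: heading itself is the
            # uniform initial heading, the drawn turn applies thereafter
            first = False
        else:
            heading = (heading + turn) % 360.0
        new_lat, new_lon = destination_arr(cur_lat, cur_lon, heading, step)
        # reference for the next turn is the arrival (final) bearing of this
        # arc, so a zero turn continues along the same great circle and the
        # simulated turning angles match extract_steps_angles exactly
        heading = (initial_bearing_arr(new_lat, new_lon, cur_lat, cur_lon) + 180.0) % 360.0
        cur_lat, cur_lon = new_lat, new_lon
        if day in record:
            i = record[day]
            lats[:, i], lons[:, i] = cur_lat, cur_lon
    return lats, lons


def simulate_segment(
    model: str,
    start: GeoPosition,
    dates: list[_dt.date],
    stats: MonthlyMovementStats,
    rng: np.random.Generator,
    levy: Optional[LevyParams] = None,
    brownian_space: str = "log",
) -> list[GeoPosition]:
    """Single-replicate convenience wrapper around segment simulation."""
    lats, lons = simulate_segment_many(
        model, start, dates, stats, rng, 1, levy, brownian_space
    )
    return [GeoPosition(float(a), float(b)) for a, b in zip(lats[0], lons[0])]


# ---------------------------------------------------------------------------
# monthly-restart driver
# ---------------------------------------------------------------------------

def _month_segments(dates: list[_dt.date]) -> list[list[int]]:
    """Indices of the source dates grouped by calendar (year, month)."""
    segs: list[list[int]] = []
    key = None
    for i, d in enumerate(dates):
        k = (d.year, d.month)
        if k != key:
            segs.append([])
            key = k
        segs[-1].append(i)
    return segs


def _segment_rng(seed: int, track_id: str, model: str, seg_idx: int) -> np.random.Generator:
    tid_hash = zlib.crc32(track_id.encode("utf-8"))
    ss = np.random.SeedSequence([int(seed), tid_hash, _MODEL_CODE[model], seg_idx])
    return np.random.default_rng(ss)


def generate_pseudo_tracks(
    source: Track,
    config: NullModelConfig,
    stats: MonthlyMovementStats,
) -> PseudoTrackSet:
    """Cohort of pseudo-absence tracks date-aligned with ``source``.

    The source's date span is cut at calendar-month boundaries. Each
    segment starts at the source's observed position on the segment's
    first date (the deployment fix for the first segment; thereafter the
    fix dated the 1st, or the earliest fix of that month when the 1st is
    missing) and is simulated independently — headings do not carry across
    restarts. Replicates share dates with the source one-to-one.
    """
    dates = source.dates
    lats_src, lons_src = source.lats(), source.lons()
    n_rep, n_fix = config.n_replicates, len(dates)
    lats = np.empty((n_rep, n_fix))
    lons = np.empty((n_rep, n_fix))
    levy = config.levy
    if config.model == "levy" and levy is None:
        levy = default_levy_params(stats)
    for seg_idx, idxs in enumerate(_month_segments(dates)):
        anchor = GeoPosition(float(lats_src[idxs[0]]), float(lons_src[idxs[0]]))
        seg_dates = [dates[i] for i in idxs]
        rng = _segment_rng(config.seed, source.track_id, config.model, seg_idx)
        seg_lats, seg_lons = simulate_segment_many(
            config.model, anchor, seg_dates, stats, rng,
            n_replicates=n_rep, levy=levy, brownian_space=config.brownian_space,
        )
        lats[:, idxs] = seg_lats
        lons[:, idxs] = seg_lons
    meta = {"seed": config.seed, "n_replicates": n_rep}
    if config.model == "levy":
        meta["levy"] = {"mu": levy.mu, "l_min": levy.l_min, "l_max": levy.l_max}
    if config.model == "brownian":
        meta["brownian_space"] = config.brownian_space
    return PseudoTrackSet(source.track_id, config.model, dates, lats, lons, meta)
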