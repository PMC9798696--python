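"""Synthetic presence tracks with prescribed SST selection strength.

A biased random walk takes fixed 50 km daily steps whose turning angles
follow a Von Mises distribution centred on the relative bearing of the
warmest SST cell within a 50 km search radius. The concentration kappa
sets the selection strength: kappa = 0 is an unbiased (uniform-heading)
walk, large kappa marches almost straight up the local SST gradient.
These tracks serve as "presence" data of known selection strength for
power and error-rate studies; their positions are exact (no positional
CI), so SST matching uses plain point sampling.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .env import EnvField, _bearing_to_max_one
from .geo import (
    GeoPosition,
    TimedFix,
    Track,
    TrackSet,
    destination_arr,
    initial_bearing_arr,
    wrap_angle_deg,
)

__all__ = [
    "VonMisesParams",
    "BiasedWalkConfig",
    "KAPPA_GRID",
    "sample_von_mises",
    "simulate_biased_track",
    "simulate_cohort",
]

# selection strengths used throughout the synthetic-track study
KAPPA_GRID = (0.0, 0.25, 0.5, 0.75, 1.0, 2.0, 5.0, 10.0, 20.0)


@dataclass(frozen=True)
class VonMisesParams:
    """Von Mises circular distribution: mean direction and concentration."""

    kappa: float
    center_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")


def sample_von_mises(params: VonMisesParams, rng: np.random.Generator, size=None):
    """Draw(s) from VM(center, kappa), degrees wrapped to (-180, 180].

    kappa = 0 reduces to the uniform circular distribution.
    """
    draws = rng.vonmises(np.radians(params.center_deg), params.kappa, size=size)
    return wrap_angle_deg(np.degrees(draws))


@dataclass
class BiasedWalkConfig:
    """One synthetic presence track: 80 daily 50 km steps by default."""

    kappa: float
    n_days: int = 80
    step_km: float = 50.0
    search_radius_km: float = 50.0
    start: Optional[GeoPosition] = None
    start_date: Optional[_dt.date] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.n_days < 1 or self.step_km <= 0 or self.search_radius_km <= 0:
            raise ValueError("n_days, step_km, search_radius_km must be positive")


def _resolve_start(config: BiasedWalkConfig, field: EnvField) -> tuple[GeoPosition, _dt.date]:
    start = config.start
    if start is None:
        start = GeoPosition(float(np.mean(field.lats)), float(np.mean(field.lons)))
    date = config.start_date or field.start_date
    return start, date


def simulate_biased_track(
    config: BiasedWalkConfig,
    field: EnvField,
    rng: Optional[np.random.Generator] = None,
    track_id: str = "biased",
) -> Track:
    """Simulate one biased track of ``n_days`` daily fixes on ``field``.

    Each day the walker senses the warmest SST cell within the search
    radius of its current position (on the current date) and draws its
    turning angle from VM(relative bearing to that cell, kappa); when the
    search finds nothing (clouds, domain edge) the centre is 0 deg, i.e.
    the heading persists. Steps are exactly ``step_km`` long. The first
    heading is uniform.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    start, date0 = _resolve_start(config, field)
    lat, lon = start.lat, start.lon
    i0, j0, inside = field.cell_indices(lat, lon, strict=False)
    if not np.all(inside):
        raise ValueError("start position outside the SST field")
    end_date = date0 + _dt.timedelta(days=config.n_days - 1)
    if np.datetime64(end_date, "D") > field.times[-1]:
        raise ValueError("track dates extend past the field's time span")

    fixes = [TimedFix(date0, GeoPosition(lat, lon))]
    heading = float(rng.uniform(0.0, 360.0))
    t0 = field.time_index(date0)
    for k in range(config.n_days - 1):
        i, j, ins = field.cell_indices(lat, lon, strict=False)
        if ins:
            target = _bearing_to_max_one(
                field, lat, lon, t0 + k, config.search_radius_km, int(i), int(j)
            )
        else:
            target = float("nan")
        center = 0.0 if np.isnan(target) else float(wrap_angle_deg(target - heading))
        turn = float(sample_von_mises(VonMisesParams(config.kappa, center), rng))
        heading = (heading + turn) % 360.0
        lat_a, lon_a = destination_arr(lat, lon, heading, config.step_km)
        # carry the arrival bearing so zero turns continue the geodesic
        heading = float(
            (initial_bearing_arr(float(lat_a), float(lon_a), lat, lon) + 180.0) % 360.0
        )
        lat, lon = float(lat_a), float(lon_a)
        fixes.append(TimedFix(date0 + _dt.timedelta(days=k + 1), GeoPosition(lat, lon)))
    return Track(track_id, fixes)


def simulate_cohort(
    kappas: Sequence[float],
    n_tracks_per_kappa: int,
    config: BiasedWalkConfig,
    field: EnvField,
    seed: int = 0,
    start_region: Optional[tuple[float, float, float, float]] = None,
) -> dict[float, TrackSet]:
    """Seeded cohorts of biased tracks for each selection strength.

    ``config`` is the per-track template (its kappa/seed/start are
    overridden). Start positions are drawn uniformly from ``start_region``
    (lat_min, lat_max, lon_min, lon_max); the default region is the
    poleward interior of the field — the cool side of the meridional
    gradient, mirroring deployments in cool foraging grounds with warm
    water available equatorward — so that warm-selecting tracks have room
    to run before meeting the domain edge.
    """
    if start_region is None:
        lat0, lat1 = field.lats[0], field.lats[-1]
        lon0, lon1 = field.lons[0], field.lons[-1]
        start_region = (
            lat0 + 0.60 * (lat1 - lat0),
            lat0 + 0.90 * (lat1 - lat0),
            lon0 + 0.15 * (lon1 - lon0),
            lon0 + 0.85 * (lon1 - lon0),
        )
    la0, la1, lo0, lo1 = start_region
    cohorts: dict[float, TrackSet] = {}
    for ik, kappa in enumerate(kappas):
        tracks = []
        for it in range(n_tracks_per_kappa):
            rng = np.random.default_rng(np.random.SeedSequence([int(seed), ik, it]))
            start = GeoPosition(float(rng.uniform(la0, la1)), float(rng.uniform(lo0, lo1)))
            cfg = BiasedWalkConfig(
                kappa=float(kappa),
                n_days=config.n_days,
                step_km=config.step_km,
                search_radius_km=config.search_radius_km,
                start=start,
                start_date=config.start_date,
            )
            tracks.append(
                simulate_biased_track(cfg, field, rng, track_id=f"kappa{kappa:g}_t{it:03d}")
            )
        cohorts[float(kappa)] = TrackSet(tracks)
    return cohorts
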