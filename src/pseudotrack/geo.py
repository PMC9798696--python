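"""Spherical geometry primitives and the track data model.

All geometry is great-circle on a sphere of radius 6371.0088 km (IUGG mean
Earth radius). Bearings are degrees clockwise from true north in [0, 360);
turning angles are signed degrees in (-180, 180], positive = clockwise
(rightward) turn. Scalar functions operate on :class:`GeoPosition`; the
``*_arr`` variants are vectorised over numpy arrays of lat/lon degrees and
are what the simulators use internally.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0088

__all__ = [
    "EARTH_RADIUS_KM",
    "GeoPosition",
    "TimedFix",
    "Track",
    "TrackSet",
    "TrackValidationError",
    "great_circle_distance",
    "initial_bearing",
    "destination_point",
    "signed_turning_angle",
    "normalize_lon",
    "wrap_angle_deg",
    "read_tracks",
    "write_tracks",
]


class TrackValidationError(ValueError):
    """Raised when track data violate the track invariants."""


def normalize_lon(lon):
    """Normalise longitude(s) to (-180, 180]."""
    return 180.0 - (180.0 - np.asarray(lon, dtype=float)) % 360.0


def wrap_angle_deg(angle):
    """Wrap angle(s) in degrees to (-180, 180]."""
    return 180.0 - (180.0 - np.asarray(angle, dtype=float)) % 360.0


@dataclass(frozen=True)
class GeoPosition:
    """A point on the globe, degrees north / degrees east.

    Longitude is normalised to (-180, 180] on construction.
    """

    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.lat) or not np.isfinite(self.lon):
            raise TrackValidationError(f"non-finite coordinates ({self.lat}, {self.lon})")
        if not -90.0 <= self.lat <= 90.0:
            raise TrackValidationError(f"latitude {self.lat} outside [-90, 90]")
        object.__setattr__(self, "lat", float(self.lat))
        object.__setattr__(self, "lon", float(normalize_lon(self.lon)))


@dataclass(frozen=True)
class TimedFix:
    """A dated position estimate with optional 95% CI radius (km)."""

    date: _dt.date
    position: GeoPosition
    ci95_km: Optional[float] = None

    def __post_init__(self) -> None:
        if self.ci95_km is not None:
            if not np.isfinite(self.ci95_km) or self.ci95_km < 0:
                raise TrackValidationError(f"ci95_km must be >= 0, got {self.ci95_km}")


@dataclass
class Track:
    """An ordered daily track: >= 2 fixes, dates strictly increasing.

    Nominal spacing is one fix per day; gaps are allowed and surface as
    per-step ``dt_days`` in downstream consumers.
    """

    track_id: str
    fixes: list[TimedFix]

    def __post_init__(self) -> None:
        if len(self.fixes) < 2:
            raise TrackValidationError(
                f"track {self.track_id!r} has {len(self.fixes)} fix(es); needs >= 2"
            )
        dates = [f.date for f in self.fixes]
        for i in range(1, len(dates)):
            if dates[i] <= dates[i - 1]:
                raise TrackValidationError(
                    f"track {self.track_id!r}: dates not strictly increasing at row {i} "
                    f"({dates[i - 1]} -> {dates[i]})"
                )

    def __len__(self) -> int:
        return len(self.fixes)

    @property
    def dates(self) -> list[_dt.date]:
        return [f.date for f in self.fixes]

    def lats(self) -> np.ndarray:
        return np.array([f.position.lat for f in self.fixes])

    def lons(self) -> np.ndarray:
        return np.array([f.position.lon for f in self.fixes])


@dataclass
class TrackSet:
    tracks: list[Track] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [t.track_id for t in self.tracks]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise TrackValidationError(f"duplicate track_ids: {dupes}")

    def __iter__(self) -> Iterator[Track]:
        return iter(self.tracks)

    def __len__(self) -> int:
        return len(self.tracks)


# ---------------------------------------------------------------------------
# vectorised great-circle kernels (degrees in, degrees/km out)
# ---------------------------------------------------------------------------

def great_circle_km_arr(lat1, lon1, lat2, lon2):
    """Haversine distance in km, elementwise over arrays of degrees."""
    p1, l1, p2, l2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dphi = p2 - p1
    dlam = l2 - l1
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    a = np.clip(a, 0.0, 1.0)
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def initial_bearing_arr(lat1, lon1, lat2, lon2):
    """Forward azimuth in degrees clockwise from north, in [0, 360)."""
    p1, l1, p2, l2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlam = l2 - l1
    y = np.sin(dlam) * np.cos(p2)
    x = np.cos(p1) * np.sin(p2) - np.sin(p1) * np.cos(p2) * np.cos(dlam)
    return np.degrees(np.arctan2(y, x)) % 360.0


def destination_arr(lat, lon, bearing_deg, distance_km):
    """Great-circle destination point(s); returns (lat, lon) degrees."""
    phi = np.radians(np.asarray(lat, dtype=float))
    lam = np.radians(np.asarray(lon, dtype=float))
    theta = np.radians(np.asarray(bearing_deg, dtype=float))
    delta = np.asarray(distance_km, dtype=float) / EARTH_RADIUS_KM
    sin_phi2 = np.sin(phi) * np.cos(delta) + np.cos(phi) * np.sin(delta) * np.cos(theta)
    sin_phi2 = np.clip(sin_phi2, -1.0, 1.0)
    phi2 = np.arcsin(sin_phi2)
    y = np.sin(theta) * np.sin(delta) * np.cos(phi)
    x = np.cos(delta) - np.sin(phi) * sin_phi2
    lam2 = lam + np.arctan2(y, x)
    return np.degrees(phi2), normalize_lon(np.degrees(lam2))


# ---------------------------------------------------------------------------
# scalar API
# ---------------------------------------------------------------------------

def great_circle_distance(a: GeoPosition, b: GeoPosition) -> float:
    """Great-circle (haversine) distance between two positions, km."""
    return float(great_circle_km_arr(a.lat, a.lon, b.lat, b.lon))


def initial_bearing(a: GeoPosition, b: GeoPosition) -> float:
    """Initial great-circle bearing a->b, degrees in [0, 360).

    Raises ValueError for coincident points (bearing undefined).
    """
    if a.lat == b.lat and a.lon == b.lon:
        raise ValueError("bearing undefined for coincident points")
    return float(initial_bearing_arr(a.lat, a.lon, b.lat, b.lon))


def destination_point(start: GeoPosition, bearing: float, distance: float) -> GeoPosition:
    """Point reached from ``start`` along ``bearing`` after ``distance`` km."""
    if distance < 0:
        raise ValueError("distance must be >= 0")
    lat, lon = destination_arr(start.lat, start.lon, bearing, distance)
    return GeoPosition(float(lat), float(lon))


def signed_turning_angle(prev_bearing: float, next_bearing: float) -> float:
    """Signed turn from one bearing to the next, degrees in (-180, 180]."""
    return float(wrap_angle_deg(next_bearing - prev_bearing))


# ---------------------------------------------------------------------------
# track file I/O (CSV dialect: track_id,date,lat,lon[,ci95_km])
# ---------------------------------------------------------------------------

_REQUIRED_COLS = ("track_id", "date", "lat", "lon")


def tracks_from_dataframe(df: pd.DataFrame) -> TrackSet:
    for col in _REQUIRED_COLS:
        if col not in df.columns:
            raise TrackValidationError(f"missing required column {col!r}")
    has_ci = "ci95_km" in df.columns
    tracks: list[Track] = []
    for tid, grp in df.groupby("track_id", sort=False):
        fixes = []
        seen_dates: set = set()
        for row in grp.itertuples():
            date = _parse_date(row.date, row.Index)
            if date in seen_dates:
                raise TrackValidationError(
                    f"track {tid!r}: duplicate date {date} (row {row.Index})"
                )
            seen_dates.add(date)
            try:
                pos = GeoPosition(float(row.lat), float(row.lon))
            except TrackValidationError as exc:
                raise TrackValidationError(f"row {row.Index}: {exc}") from exc
            ci = None
            if has_ci:
                raw = getattr(row, "ci95_km")
                if raw is not None and not pd.isna(raw):
                    ci = float(raw)
            fixes.append(TimedFix(date, pos, ci))
        fixes.sort(key=lambda f: f.date)
        dates = [f.date for f in fixes]
        orig = [_parse_date(r.date, r.Index) for r in grp.itertuples()]
        if orig != dates:
            raise TrackValidationError(f"track {tid!r}: dates out of order in file")
        tracks.append(Track(str(tid), fixes))
    return TrackSet(tracks)


def _parse_date(value, row) -> _dt.date:
    if isinstance(value, _dt.date) and not isinstance(value, _dt.datetime):
        return value
    try:
        return _dt.date.fromisoformat(str(value)[:10])
    except ValueError as exc:
        raise TrackValidationError(f"row {row}: unparseable date {value!r}") from exc


def tracks_to_dataframe(ts: TrackSet, extra: Optional[dict] = None) -> pd.DataFrame:
    rows = []
    for track in ts:
        for f in track.fixes:
            rows.append(
                {
                    "track_id": track.track_id,
                    "date": f.date.isoformat(),
                    "lat": f.position.lat,
                    "lon": f.position.lon,
                    "ci95_km": f.ci95_km,
                }
            )
    df = pd.DataFrame(rows)
    if extra:
        for k, v in extra.items():
            df[k] = v
    return df


def read_tracks(path) -> TrackSet:
    """Read a track CSV (``track_id,date,lat,lon[,ci95_km]``) and validate."""
    df = pd.read_csv(path)
    return tracks_from_dataframe(df)


def write_tracks(ts: TrackSet, path) -> None:
    """Write a TrackSet to the track CSV dialect (round-trips exactly)."""
    tracks_to_dataframe(ts).to_csv(path, index=False)
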