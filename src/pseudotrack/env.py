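"""Gridded SST field: data model, NetCDF I/O, rolling mean, and sampling.

The field is a regular (time, lat, lon) grid of sea-surface temperature in
degrees Celsius with NaN marking missing cells (clouds, land, no retrieval).
Sampling is nearest-cell: the value attributed to a position is that of the
grid cell containing it, which keeps missingness semantics simple at the
~9 km resolution this package targets. Positions with a positional 95% CI
are sampled with a truncated-Gaussian weighted mean instead (sigma = a
configurable fraction of the CI radius, 0.25 by default).
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass

import numpy as np
import xarray as xr

from .geo import GeoPosition, Track, great_circle_km_arr, initial_bearing_arr

logger = logging.getLogger(__name__)

__all__ = [
    "EnvField",
    "UncertaintyModel",
    "TrackSamples",
    "EnvValidationError",
    "OutOfDomainError",
    "read_env",
    "write_env",
    "backward_rolling_mean",
    "sample_point",
    "sample_weighted",
    "bearing_to_max_sst",
    "match_track_to_env",
]


class EnvValidationError(ValueError):
    """Raised when a gridded field violates the grid invariants."""


class OutOfDomainError(ValueError):
    """Raised when a queried position/date falls outside the grid."""


def _check_regular(axis: np.ndarray, name: str, tol: float = 1e-9) -> float:
    if axis.ndim != 1 or axis.size < 2:
        raise EnvValidationError(f"{name} axis must be 1-D with >= 2 points")
    d = np.diff(axis)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise EnvValidationError(f"{name} axis must be strictly monotone")
    if np.ptp(d) > tol:
        raise EnvValidationError(f"{name} axis spacing not constant (ptp={np.ptp(d):g})")
    return float(d[0])


@dataclass
class EnvField:
    """Regular (time, lat, lon) SST grid in deg C; NaN = missing."""

    times: np.ndarray  # datetime64[D], strictly increasing
    lats: np.ndarray  # degrees, regular
    lons: np.ndarray  # degrees, regular
    sst: np.ndarray  # (time, lat, lon) float, NaN missing
    cell_size_km: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype="datetime64[D]")
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        self.sst = np.asarray(self.sst, dtype=float)
        if self.sst.shape != (self.times.size, self.lats.size, self.lons.size):
            raise EnvValidationError(
                f"sst shape {self.sst.shape} does not match axes "
                f"({self.times.size}, {self.lats.size}, {self.lons.size})"
            )
        if np.any(np.diff(self.times).astype(int) <= 0):
            raise EnvValidationError("time axis must be strictly increasing")
        self._dlat = _check_regular(self.lats, "lat")
        self._dlon = _check_regular(self.lons, "lon")
        # store axes ascending so index arithmetic and windowing stay simple
        if self._dlat < 0:
            self.lats = self.lats[::-1].copy()
            self.sst = self.sst[:, ::-1, :].copy()
            self._dlat = -self._dlat
        if self._dlon < 0:
            self.lons = self.lons[::-1].copy()
            self.sst = self.sst[:, :, ::-1].copy()
            self._dlon = -self._dlon
        if np.any(np.abs(self.lats) > 90.0):
            raise EnvValidationError("latitudes outside [-90, 90]")
        if self.cell_size_km is None:
            # nominal: meridional extent of one cell
            self.cell_size_km = abs(self._dlat) * 111.195
        if self.cell_size_km <= 0:
            raise EnvValidationError("cell_size_km must be positive")

    # -- index helpers ----------------------------------------------------
    def time_index(self, date) -> int:
        d = np.datetime64(date, "D")
        idx = int(np.searchsorted(self.times, d))
        if idx >= self.times.size or self.times[idx] != d:
            raise OutOfDomainError(f"date {d} not on the field's time axis")
        return idx

    def _axis_index(self, axis: np.ndarray, step: float, values) -> np.ndarray:
        # nearest cell centre; exact midpoints resolve to the lower index
        frac = (np.asarray(values, dtype=float) - axis[0]) / step
        idx = np.ceil(frac - 0.5).astype(int)
        return idx

    def cell_indices(self, lats, lons, strict: bool = True):
        """Nearest-cell (i, j) indices for positions; ties -> lower index."""
        i = self._axis_index(self.lats, self._dlat, lats)
        j = self._axis_index(self.lons, self._dlon, lons)
        inside = (i >= 0) & (i < self.lats.size) & (j >= 0) & (j < self.lons.size)
        if strict and not np.all(inside):
            raise OutOfDomainError("position outside the grid bounding box")
        return i, j, inside

    @property
    def start_date(self) -> _dt.date:
        return self.times[0].astype("datetime64[D]").astype(_dt.date)

    @property
    def end_date(self) -> _dt.date:
        return self.times[-1].astype("datetime64[D]").astype(_dt.date)

    def to_xarray(self) -> xr.Dataset:
        return xr.Dataset(
            {"sst": (("time", "lat", "lon"), self.sst)},
            coords={
                "time": self.times.astype("datetime64[ns]"),
                "lat": self.lats,
                "lon": self.lons,
            },
            attrs={"cell_size_km": self.cell_size_km},
        )


@dataclass(frozen=True)
class UncertaintyModel:
    """Gaussian positional-error model for SST sampling.

    sigma = ``sigma_fraction`` x ci95_km (0.25: sigma is a quarter of the
    95% CI radius); cells beyond ``truncation_sigmas`` x sigma get zero
    weight (3 sigma captures ~98.9% of the 2-D Gaussian mass).
    """

    sigma_fraction: float = 0.25
    truncation_sigmas: float = 3.0

    def __post_init__(self) -> None:
        if self.sigma_fraction <= 0 or self.truncation_sigmas <= 0:
            raise ValueError("sigma_fraction and truncation_sigmas must be > 0")


# ---------------------------------------------------------------------------
# I/O (NetCDF-3 through xarray's scipy backend)
# ---------------------------------------------------------------------------

def write_env(field: EnvField, path) -> None:
    """Write the field to NetCDF (dims time/lat/lon, variable ``sst``)."""
    field.to_xarray().to_netcdf(path, engine="scipy")


def read_env(path) -> EnvField:
    """Read a NetCDF SST field; validates grid regularity and time order."""
    with xr.open_dataset(path, engine="scipy") as ds:
        if "sst" not in ds:
            raise EnvValidationError(f"{path}: expected variable 'sst', found {list(ds.data_vars)}")
        da = ds["sst"].transpose("time", "lat", "lon")
        field = EnvField(
            times=ds["time"].values.astype("datetime64[D]"),
            lats=ds["lat"].values,
            lons=ds["lon"].values,
            sst=da.values.astype(float),
            cell_size_km=float(ds.attrs.get("cell_size_km", 0)) or None,
        )
    return field


# ---------------------------------------------------------------------------
# temporal compositing
# ---------------------------------------------------------------------------

def backward_rolling_mean(field: EnvField, window_days: int) -> EnvField:
    """Backward rolling mean over ``window_days``, ignoring missing values.

    The value at day t is the mean of the non-missing values on days
    (t - window + 1) .. t per cell; a cell stays missing only if every day
    in its window is missing. Mirrors the 8-day backward compositing used
    to increase satellite SST coverage.
    """
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    if window_days == 1:
        return EnvField(field.times.copy(), field.lats.copy(), field.lons.copy(),
                        field.sst.copy(), field.cell_size_km)
    vals = np.nan_to_num(field.sst, nan=0.0)
    cnts = (~np.isnan(field.sst)).astype(float)
    csum = np.cumsum(vals, axis=0)
    ccnt = np.cumsum(cnts, axis=0)
    zeros = np.zeros((1,) + field.sst.shape[1:])
    csum = np.concatenate([zeros, csum], axis=0)
    ccnt = np.concatenate([zeros, ccnt], axis=0)
    nt = field.sst.shape[0]
    lo = np.maximum(np.arange(nt) - window_days + 1, 0)
    wsum = csum[1:] - csum[lo]
    wcnt = ccnt[1:] - ccnt[lo]
    with np.errstate(invalid="ignore"):
        out = np.where(wcnt > 0, wsum / np.where(wcnt > 0, wcnt, 1.0), np.nan)
    return EnvField(field.times.copy(), field.lats.copy(), field.lons.copy(), out,
                    field.cell_size_km)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def sample_point(field: EnvField, position: GeoPosition, date) -> float:
    """SST of the grid cell containing ``position`` on ``date`` (NaN if missing)."""
    t = field.time_index(date)
    i, j, _ = field.cell_indices(position.lat, position.lon)
    return float(field.sst[t, int(i), int(j)])


def sample_point_many(field: EnvField, lats, lons, tidx) -> np.ndarray:
    """Vectorised nearest-cell sampling; out-of-grid positions return NaN."""
    i, j, inside = field.cell_indices(lats, lons, strict=False)
    out = np.full(np.shape(i), np.nan, dtype=float)
    t = np.broadcast_to(np.asarray(tidx), out.shape)
    out[inside] = field.sst[t[inside], i[inside], j[inside]]
    return out


def sample_weighted(
    field: EnvField,
    position: GeoPosition,
    date,
    ci95_km: float,
    model: UncertaintyModel = UncertaintyModel(),
) -> float:
    """Gaussian-weighted SST around an uncertain position.

    sigma = sigma_fraction x ci95_km. Non-missing cells whose centres lie
    within truncation_sigmas x sigma get weight exp(-d^2 / (2 sigma^2)),
    d the great-circle distance to the cell centre. Degenerates to
    :func:`sample_point` when sigma is below half a cell. NaN if every cell
    in the window is missing.
    """
    if ci95_km < 0:
        raise ValueError("ci95_km must be >= 0")
    sigma = model.sigma_fraction * ci95_km
    if sigma < 0.5 * field.cell_size_km:
        return sample_point(field, position, date)
    t = field.time_index(date)
    radius_km = model.truncation_sigmas * sigma
    ci, cj, lat_g, lon_g = _window(field, position, radius_km)
    d = great_circle_km_arr(position.lat, position.lon, lat_g, lon_g)
    sst = field.sst[t, ci, cj]
    ok = (d <= radius_km) & ~np.isnan(sst)
    if not np.any(ok):
        return float("nan")
    w = np.exp(-d[ok] ** 2 / (2.0 * sigma**2))
    return float(np.sum(w * sst[ok]) / np.sum(w))


def _window(field: EnvField, position: GeoPosition, radius_km: float):
    """Grid index window guaranteed to contain all cells within radius_km."""
    ddeg_lat = radius_km / 111.195 + abs(field._dlat)
    coslat = max(np.cos(np.radians(position.lat)), 1e-6)
    ddeg_lon = radius_km / (111.195 * coslat) + abs(field._dlon)
    i0 = int(np.searchsorted(field.lats, position.lat - ddeg_lat, "left"))
    i1 = int(np.searchsorted(field.lats, position.lat + ddeg_lat, "right"))
    j0 = int(np.searchsorted(field.lons, position.lon - ddeg_lon, "left"))
    j1 = int(np.searchsorted(field.lons, position.lon + ddeg_lon, "right"))
    ci, cj = np.meshgrid(np.arange(i0, i1), np.arange(j0, j1), indexing="ij")
    ci, cj = ci.ravel(), cj.ravel()
    return ci, cj, field.lats[ci], field.lons[cj]


def bearing_to_max_sst(
    field: EnvField, position: GeoPosition, date, radius_km: float
) -> float:
    """Bearing (deg) to the warmest cell centre within ``radius_km``.

    The cell containing the position is excluded. Ties are broken by
    smallest distance, then by (lat, lon) axis order. Returns NaN when no
    eligible non-missing cell exists.
    """
    if radius_km <= 0:
        raise ValueError("radius_km must be > 0")
    t = field.time_index(date)
    i_self, j_self, _ = field.cell_indices(position.lat, position.lon)
    return _bearing_to_max_one(field, float(position.lat), float(position.lon),
                               t, radius_km, int(i_self), int(j_self))


def _bearing_to_max_one(field, lat, lon, t, radius_km, i_self, j_self) -> float:
    ci, cj, lat_g, lon_g = _window(field, GeoPosition(lat, lon), radius_km)
    d = great_circle_km_arr(lat, lon, lat_g, lon_g)
    sst = field.sst[t, ci, cj]
    ok = (d <= radius_km) & ~np.isnan(sst) & ~((ci == i_self) & (cj == j_self))
    if not np.any(ok):
        return float("nan")
    ci, cj, lat_g, lon_g, d, sst = (a[ok] for a in (ci, cj, lat_g, lon_g, d, sst))
    # lexicographic argmax: SST desc, then distance asc, then (i, j) asc
    order = np.lexsort((cj, ci, d, -sst))
    k = order[0]
    return float(initial_bearing_arr(lat, lon, lat_g[k], lon_g[k]))


# ---------------------------------------------------------------------------
# track matching
# ---------------------------------------------------------------------------

@dataclass
class TrackSamples:
    """SST values matched to a track's fixes; missing fixes dropped."""

    track_id: str
    dates: np.ndarray  # datetime64[D], retained fixes only
    sst: np.ndarray  # deg C
    n_dropped: int

    def __len__(self) -> int:
        return self.sst.size


def match_track_to_env(
    track: Track,
    field: EnvField,
    model: UncertaintyModel = UncertaintyModel(),
) -> TrackSamples:
    """Match every fix to SST; weighted sampling where a 95% CI is present.

    Fixes whose sample is missing (cloud/land gap or out-of-grid) are
    dropped and counted in ``n_dropped``; an all-missing track raises.
    """
    dates, values = [], []
    n_dropped = 0
    for fix in track.fixes:
        try:
            if fix.ci95_km is not None:
                v = sample_weighted(field, fix.position, fix.date, fix.ci95_km, model)
            else:
                v = sample_point(field, fix.position, fix.date)
        except OutOfDomainError:
            v = float("nan")
        if np.isnan(v):
            n_dropped += 1
        else:
            dates.append(np.datetime64(fix.date, "D"))
            values.append(v)
    if not values:
        raise ValueError(f"track {track.track_id!r}: every fix fell on missing SST")
    if n_dropped:
        logger.info("track %s: dropped %d of %d fixes (missing SST)",
                    track.track_id, n_dropped, len(track.fixes))
    return TrackSamples(track.track_id, np.array(dates, dtype="datetime64[D]"),
                        np.array(values), n_dropped)
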