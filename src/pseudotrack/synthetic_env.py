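"""Synthetic sea-surface temperature fields for simulation studies.

Generates a daily SST grid with the statistical structure the selection
tests are sensitive to: a basin-scale meridional gradient, mesoscale
(eddy-like) anomalies with prescribed spatial and temporal correlation
scales, a seasonal cycle, white observation noise, and spatially clumped
missingness mimicking cloud masks. It is a statistical emulator of a
satellite SST product, not an ocean model.

The default configuration is "northeast-Pacific-like": 20-45 N, 150-115 W
at ~9 km (0.0833 deg) resolution, 22 C at the southern edge cooling by
0.35 C per degree of latitude northward, 1.5 C eddies at 150 km / 20 days,
a 2 C seasonal cycle, 0.2 C noise, and 10% clumped missingness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .env import EnvField

__all__ = ["SyntheticEnvConfig", "generate_env"]


@dataclass
class SyntheticEnvConfig:
    """Parameters of the synthetic SST field (degrees, km, days, deg C)."""

    lat_min: float = 20.0
    lat_max: float = 45.0
    lon_min: float = -150.0
    lon_max: float = -115.0
    cell_size_deg: float = 1.0 / 12.0  # ~9 km
    n_days: int = 100
    start_date: str = "2004-01-01"
    base_sst: float = 22.0  # at lat_min
    meridional_gradient: float = -0.35  # deg C per degree latitude northward
    eddy_amplitude: float = 1.5  # deg C (std of the anomaly field)
    eddy_length_scale_km: float = 150.0  # e-folding of spatial correlation
    eddy_time_scale_days: float = 20.0  # e-folding of temporal correlation
    seasonal_amplitude: float = 2.0  # deg C
    noise_sd: float = 0.2  # deg C, white
    missing_fraction: float = 0.10
    missing_length_scale_km: float = 100.0  # clump scale of the cloud mask
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lat_max <= self.lat_min or self.lon_max <= self.lon_min:
            raise ValueError("empty spatial extent")
        if self.cell_size_deg <= 0 or self.n_days < 1:
            raise ValueError("cell size and n_days must be positive")
        for name in ("eddy_length_scale_km", "eddy_time_scale_days",
                     "missing_length_scale_km"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must be in [0, 1)")


def _smooth_unit_noise(rng: np.random.Generator, shape, sigma_cells: float) -> np.ndarray:
    """Gaussian-smoothed white noise rescaled to unit variance."""
    raw = rng.standard_normal(shape)
    sm = ndimage.gaussian_filter(raw, sigma=sigma_cells, mode="reflect")
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def generate_env(config: SyntheticEnvConfig) -> EnvField:
    """Generate a reproducible synthetic SST field from ``config``.

    SST(t, lat, lon) = base + gradient*(lat - lat_min)
                     + seasonal_amplitude * sin(2 pi t / 365)
                     + eddy(t, lat, lon) + noise,
    with ``eddy`` an AR(1)-in-time, Gaussian-correlated-in-space random
    field whose spatial correlation e-folds at ``eddy_length_scale_km``
    and whose temporal correlation e-folds at ``eddy_time_scale_days``.
    Missing cells are drawn by thresholding a second smooth field per day,
    giving spatially clumped cloud-like gaps at ``missing_fraction``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    lats = np.arange(cfg.lat_min + cfg.cell_size_deg / 2, cfg.lat_max, cfg.cell_size_deg)
    lons = np.arange(cfg.lon_min + cfg.cell_size_deg / 2, cfg.lon_max, cfg.cell_size_deg)
    times = np.datetime64(cfg.start_date, "D") + np.arange(cfg.n_days)
    nt, ny, nx = cfg.n_days, lats.size, lons.size

    mean_lat = 0.5 * (cfg.lat_min + cfg.lat_max)
    cell_km = cfg.cell_size_deg * 111.195  # meridional; zonal is smaller by cos(lat)
    # smoothing a white field with a Gaussian kernel of std s gives a
    # Gaussian correlogram exp(-d^2 / (4 s^2)): e-folding at d = 2 s
    sigma_eddy = cfg.eddy_length_scale_km / (2.0 * cell_km)
    sigma_miss = cfg.missing_length_scale_km / (2.0 * cell_km)

    deterministic = (
        cfg.base_sst
        + cfg.meridional_gradient * (lats - cfg.lat_min)[None, :, None]
        + cfg.seasonal_amplitude * np.sin(2 * np.pi * np.arange(nt) / 365.0)[:, None, None]
    )
    sst = np.broadcast_to(deterministic, (nt, ny, nx)).astype(float).copy()

    if cfg.eddy_amplitude > 0:
        rho = float(np.exp(-1.0 / cfg.eddy_time_scale_days))
        eddy = _smooth_unit_noise(rng, (ny, nx), sigma_eddy)
        sst[0] += cfg.eddy_amplitude * eddy
        for t in range(1, nt):
            innov = _smooth_unit_noise(rng, (ny, nx), sigma_eddy)
            eddy = rho * eddy + np.sqrt(1.0 - rho**2) * innov
            sst[t] += cfg.eddy_amplitude * eddy

    if cfg.noise_sd > 0:
        sst += cfg.noise_sd * rng.standard_normal((nt, ny, nx))

    if cfg.missing_fraction > 0:
        for t in range(nt):
            cloud = _smooth_unit_noise(rng, (ny, nx), sigma_miss)
            thresh = np.quantile(cloud, cfg.missing_fraction)
            sst[t][cloud <= thresh] = np.nan

    return EnvField(times=times, lats=lats, lons=lons, sst=sst,
                    cell_size_km=cell_km)
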