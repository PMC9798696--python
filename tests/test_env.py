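import datetime as dt

import numpy as np
import pytest

from pseudotrack import (
    EnvField,
    GeoPosition,
    UncertaintyModel,
    backward_rolling_mean,
    bearing_to_max_sst,
    match_track_to_env,
    read_env,
    sample_point,
    sample_weighted,
    write_env,
)
from pseudotrack.env import EnvValidationError, OutOfDomainError
from pseudotrack.geo import great_circle_km_arr

from conftest import make_track

D0 = dt.date(2004, 1, 1)


def toy_field(sst, lats=None, lons=None, n_days=None):
    sst = np.asarray(sst, dtype=float)
    if sst.ndim == 2:
        sst = sst[None, :, :]
    nt, ny, nx = sst.shape
    lats = np.arange(ny, dtype=float) if lats is None else np.asarray(lats, float)
    lons = np.arange(nx, dtype=float) if lons is None else np.asarray(lons, float)
    times = np.datetime64(D0, "D") + np.arange(nt)
    return EnvField(times=times, lats=lats, lons=lons, sst=sst)


class TestEnvIO:
    def test_roundtrip_with_mask(self, tmp_path):
        sst = np.arange(8, dtype=float).reshape(2, 2, 2)
        sst[0, 0, 1] = np.nan
        f = toy_field(sst)
        path = tmp_path / "f.nc"
        write_env(f, path)
        back = read_env(path)
        np.testing.assert_array_equal(back.times, f.times)
        np.testing.assert_allclose(back.lats, f.lats)
        np.testing.assert_allclose(back.lons, f.lons)
        np.testing.assert_array_equal(np.isnan(back.sst), np.isnan(f.sst))
        np.testing.assert_allclose(back.sst[~np.isnan(f.sst)], f.sst[~np.isnan(f.sst)])

    def test_missing_variable_named(self, tmp_path):
        import xarray as xr
        path = tmp_path / "bad.nc"
        xr.Dataset({"temp": (("time", "lat", "lon"), np.ones((1, 2, 2)))},
                   coords={"time": np.array(["2004-01-01"], dtype="datetime64[ns]"),
                           "lat": [0.0, 1.0], "lon": [0.0, 1.0]}).to_netcdf(
            path, engine="scipy")
        with pytest.raises(EnvValidationError, match="sst"):
            read_env(path)

    def test_irregular_grid_rejected(self):
        with pytest.raises(EnvValidationError, match="spacing"):
            toy_field(np.ones((1, 3, 3)), lats=[0.0, 1.0, 3.0])

    def test_descending_axes_normalised(self):
        f = toy_field(np.arange(9, dtype=float).reshape(1, 3, 3),
                      lats=[2.0, 1.0, 0.0])
        assert f.lats[0] < f.lats[-1]
        # value at lat=2 must still be the original row
        assert sample_point(f, GeoPosition(2.0, 0.0), D0) == 0.0


class TestRollingMean:
    def test_window_one_identity(self):
        sst = np.random.default_rng(0).normal(15, 2, size=(5, 3, 3))
        f = toy_field(sst)
        out = backward_rolling_mean(f, 1)
        np.testing.assert_array_equal(out.sst, f.sst)

    def test_skips_missing_days(self):
        series = np.ones((3, 2, 2))
        series[:, 0, 0] = [10.0, np.nan, 16.0]
        f = toy_field(series)
        out = backward_rolling_mean(f, 3)
        assert out.sst[2, 0, 0] == pytest.approx(13.0)
        assert out.sst[1, 0, 0] == pytest.approx(10.0)

    def test_all_missing_window_stays_missing(self):
        series = np.full((3, 2, 2), np.nan)
        f = toy_field(series)
        out = backward_rolling_mean(f, 2)
        assert np.isnan(out.sst).all()

    def test_matches_brute_force_and_preserves_bounds(self):
        rng = np.random.default_rng(3)
        sst = rng.normal(15, 3, size=(12, 4, 5))
        sst[rng.random(sst.shape) < 0.3] = np.nan
        f = toy_field(sst)
        out = backward_rolling_mean(f, 8)
        import warnings
        for t in range(12):
            lo = max(0, t - 7)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
                expected = np.nanmean(sst[lo:t + 1], axis=0)
            np.testing.assert_allclose(out.sst[t], expected, equal_nan=True)
        valid_in, valid_out = sst[~np.isnan(sst)], out.sst[~np.isnan(out.sst)]
        assert valid_out.min() >= valid_in.min() - 1e-12
        assert valid_out.max() <= valid_in.max() + 1e-12


class TestSamplePoint:
    def test_cell_centre(self):
        f = toy_field(np.arange(9, dtype=float).reshape(1, 3, 3))
        assert sample_point(f, GeoPosition(1.0, 2.0), D0) == 5.0

    def test_missing_cell(self):
        sst = np.ones((1, 3, 3))
        sst[0, 1, 1] = np.nan
        f = toy_field(sst)
        assert np.isnan(sample_point(f, GeoPosition(1.0, 1.0), D0))

    def test_midpoint_tie_goes_to_lower_index(self):
        f = toy_field(np.arange(9, dtype=float).reshape(1, 3, 3))
        assert sample_point(f, GeoPosition(0.5, 0.0), D0) == 0.0
        assert sample_point(f, GeoPosition(0.0, 0.5), D0) == 0.0

    def test_outside_grid_raises(self):
        f = toy_field(np.ones((1, 3, 3)))
        with pytest.raises(OutOfDomainError):
            sample_point(f, GeoPosition(10.0, 0.0), D0)

    def test_date_off_axis_raises(self):
        f = toy_field(np.ones((1, 3, 3)))
        with pytest.raises(OutOfDomainError):
            sample_point(f, GeoPosition(1.0, 1.0), dt.date(2005, 1, 1))


class TestSampleWeighted:
    def test_constant_field(self):
        f = toy_field(np.full((1, 21, 21), 15.0), lats=np.linspace(0, 2, 21),
                      lons=np.linspace(0, 2, 21))
        v = sample_weighted(f, GeoPosition(1.0, 1.0), D0, ci95_km=80.0)
        assert v == pytest.approx(15.0)

    def test_zero_ci_degrades_to_point(self):
        rng = np.random.default_rng(5)
        f = toy_field(rng.normal(15, 3, size=(1, 5, 5)))
        p = GeoPosition(2.2, 3.4)
        assert sample_weighted(f, p, D0, 0.0) == sample_point(f, p, D0)

    def test_matches_brute_force_sum(self):
        rng = np.random.default_rng(6)
        lats = np.linspace(10, 12, 25)
        lons = np.linspace(-40, -38, 25)
        sst = rng.normal(18, 2, size=(1, 25, 25))
        sst[0, rng.integers(0, 25, 40), rng.integers(0, 25, 40)] = np.nan
        f = toy_field(sst, lats=lats, lons=lons)
        p = GeoPosition(11.03, -39.01)
        model = UncertaintyModel(sigma_fraction=0.25, truncation_sigmas=3.0)
        ci = 120.0
        sigma = 0.25 * ci
        num = den = 0.0
        for i, la in enumerate(lats):
            for j, lo in enumerate(lons):
                d = float(great_circle_km_arr(p.lat, p.lon, la, lo))
                if d <= 3 * sigma and not np.isnan(sst[0, i, j]):
                    w = np.exp(-d**2 / (2 * sigma**2))
                    num += w * sst[0, i, j]
                    den += w
        assert sample_weighted(f, p, D0, ci, model) == pytest.approx(num / den, abs=1e-12)

    def test_all_missing_window(self):
        f = toy_field(np.full((1, 5, 5), np.nan), lats=np.linspace(0, 0.4, 5),
                      lons=np.linspace(0, 0.4, 5))
        assert np.isnan(sample_weighted(f, GeoPosition(0.2, 0.2), D0, 100.0))


class TestBearingToMaxSST:
    def test_northward_warming_points_north(self, gradient_field):
        f = gradient_field
        p = GeoPosition(27.0, -132.0)
        b = bearing_to_max_sst(f, p, f.start_date, 50.0)
        # within one cell's angular width of due north
        cell_angle = np.degrees(np.arctan2(f.cell_size_km, 50.0))
        assert min(b, 360 - b) <= cell_angle + 1e-6

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(7)
        lats = np.linspace(0, 2, 25)
        lons = np.linspace(0, 2, 25)
        sst = rng.normal(15, 3, size=(1, 25, 25))
        f = toy_field(sst, lats=lats, lons=lons)
        p = GeoPosition(1.0, 1.0)
        best = None
        for i, la in enumerate(lats):
            for j, lo in enumerate(lons):
                d = float(great_circle_km_arr(p.lat, p.lon, la, lo))
                if d <= 150.0 and d > 0 and not (la == p.lat and lo == p.lon):
                    key = (-sst[0, i, j], d, i, j)
                    if best is None or key < best[0]:
                        best = (key, la, lo)
        from pseudotrack.geo import initial_bearing_arr
        expected = float(initial_bearing_arr(p.lat, p.lon, best[1], best[2]))
        assert bearing_to_max_sst(f, p, D0, 150.0) == pytest.approx(expected, abs=1e-9)

    def test_all_missing_returns_nan(self):
        f = toy_field(np.full((1, 5, 5), np.nan), lats=np.linspace(0, 0.4, 5),
                      lons=np.linspace(0, 0.4, 5))
        assert np.isnan(bearing_to_max_sst(f, GeoPosition(0.2, 0.2), D0, 50.0))

    def test_uniform_field_deterministic(self):
        f = toy_field(np.full((1, 9, 9), 10.0), lats=np.linspace(0, 0.8, 9),
                      lons=np.linspace(0, 0.8, 9))
        p = GeoPosition(0.41, 0.41)
        b1 = bearing_to_max_sst(f, p, D0, 60.0)
        b2 = bearing_to_max_sst(f, p, D0, 60.0)
        assert b1 == b2

    def test_rotation_equivariance(self):
        # rotating the field 90 deg about the query point rotates the bearing
        rng = np.random.default_rng(8)
        n = 21
        lats = np.linspace(-0.5, 0.5, n)
        lons = np.linspace(-0.5, 0.5, n)
        patch = rng.normal(15, 2, size=(n, n))
        f1 = toy_field(patch[None], lats=lats, lons=lons)
        # rotate the field 90 deg counterclockwise about the query point:
        # new[i, j] = old[2c - j, i] (x = lon, y = lat plane at the equator)
        rotated = patch.T[:, ::-1]
        f2 = toy_field(rotated[None], lats=lats, lons=lons)
        p = GeoPosition(0.0, 0.0)
        b1 = bearing_to_max_sst(f1, p, D0, 40.0)
        b2 = bearing_to_max_sst(f2, p, D0, 40.0)
        assert (b1 - b2) % 360 == pytest.approx(90.0, abs=1.5)


class TestMatchTrack:
    def test_constant_field(self):
        f = toy_field(np.full((10, 5, 5), 15.0), lats=np.linspace(30, 30.4, 5),
                      lons=np.linspace(-135, -134.6, 5))
        t = make_track("a", D0, [(30.1, -134.9), (30.2, -134.8), (30.3, -134.7)])
        s = match_track_to_env(t, f)
        assert np.allclose(s.sst, 15.0)
        assert s.n_dropped == 0

    def test_missing_fix_dropped_and_counted(self):
        sst = np.full((10, 5, 5), 15.0)
        sst[1, 2, 2] = np.nan
        f = toy_field(sst, lats=np.linspace(30, 30.4, 5), lons=np.linspace(-135, -134.6, 5))
        t = make_track("a", D0, [(30.1, -134.9), (30.2, -134.8), (30.3, -134.7)])
        # second fix lands on the missing cell
        t.fixes[1] = t.fixes[1].__class__(t.fixes[1].date, GeoPosition(30.2, -134.8))
        sst[1, :, :] = np.nan
        f2 = toy_field(sst, lats=np.linspace(30, 30.4, 5), lons=np.linspace(-135, -134.6, 5))
        s = match_track_to_env(t, f2)
        assert len(s) == 2 and s.n_dropped == 1

    def test_samples_match_independent_recomputation(self, gradient_field):
        f = gradient_field
        t = make_track("g", f.start_date,
                       [(25.0, -133.0), (25.3, -133.0), (25.6, -132.8)])
        s = match_track_to_env(t, f)
        expected = [sample_point(f, fix.position, fix.date) for fix in t.fixes]
        np.testing.assert_allclose(s.sst, expected)

    def test_weighted_used_when_ci_present(self):
        rng = np.random.default_rng(9)
        f = toy_field(rng.normal(15, 2, size=(5, 25, 25)),
                      lats=np.linspace(30, 32, 25), lons=np.linspace(-135, -133, 25))
        t = make_track("w", D0, [(31.0, -134.0), (31.1, -134.0)], ci=200.0)
        s = match_track_to_env(t, f)
        expected0 = sample_weighted(f, t.fixes[0].position, t.fixes[0].date, 200.0)
        assert s.sst[0] == pytest.approx(expected0)
        assert s.sst[0] != sample_point(f, t.fixes[0].position, t.fixes[0].date)
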