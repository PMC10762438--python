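import numpy as np
import pytest
import xarray as xr

from pamscape.geodesy import destination, haversine
from pamscape.raytrace import (
    BottomSpec,
    SliceEnvironment,
    TLSlice,
    TracerConfig,
    extract_slice,
    grid_tl,
    sound_speed,
    thorp_absorption_db_per_km,
    trace_tl,
)


class TestSoundSpeed:
    def test_polar_surface_value(self):
        # independent evaluation of the nine-term polynomial at T=0, S=34, z=0:
        # 1448.96 + 1.340·(34−35) = 1447.62
        c = float(sound_speed(0.0, 34.0, 0.0))
        assert c == pytest.approx(1447.62, abs=0.01)
        assert 1440.0 <= c <= 1460.0

    def test_pressure_term_monotone_in_depth(self):
        z = np.linspace(0, 4000, 50)
        c = sound_speed(0.0, 34.0, z)
        assert np.all(np.diff(c) > 0)

    def test_warmer_water_is_faster(self):
        assert sound_speed(2.0, 34.0, 100.0) > sound_speed(0.0, 34.0, 100.0)

    def test_thorp_negligible_at_low_frequency(self):
        assert thorp_absorption_db_per_km(20.0) < 0.01
        assert thorp_absorption_db_per_km(5000.0) > thorp_absorption_db_per_km(500.0)


@pytest.fixture(scope="module")
def flat_bathy():
    lat = np.arange(-63.0, -57.0, 0.1)
    lon = np.arange(-49.0, -43.0, 0.1)
    return xr.DataArray(
        np.full((lat.size, lon.size), 1000.0),
        coords={"lat": lat, "lon": lon},
        dims=("lat", "lon"),
    )


class TestExtractSlice:
    def test_constant_depth_profile(self, flat_bathy):
        env = extract_slice(flat_bathy, -60.0, -46.0, 45.0, length_m=100_000.0)
        assert np.allclose(env.depths_m, 1000.0, atol=1e-6)

    def test_mirror_symmetry_north_south(self):
        lat = np.arange(-63.0, -57.0, 0.1)
        lon = np.arange(-49.0, -43.0, 0.1)
        centre = -60.0
        depth = 1000.0 + 50.0 * np.abs(lat - centre)[:, None] * np.ones((1, lon.size))
        bathy = xr.DataArray(depth, coords={"lat": lat, "lon": lon}, dims=("lat", "lon"))
        north = extract_slice(bathy, centre, -46.0, 0.0, length_m=100_000.0)
        south = extract_slice(bathy, centre, -46.0, 180.0, length_m=100_000.0)
        assert np.allclose(north.depths_m, south.depths_m, atol=0.5)

    def test_node_position_matches_geodesic_oracle(self, flat_bathy):
        origin = (-60.4, -45.96)
        lat1, lon1 = destination(origin[0], origin[1], 1.0, 500_000.0)
        # inverse problem closes the loop
        assert haversine(origin[0], origin[1], lat1, lon1) == pytest.approx(
            500_000.0, abs=1.0
        )

    def test_origin_on_land_rejected(self, flat_bathy):
        dry = flat_bathy.copy()
        dry.values[:] = -10.0
        with pytest.raises(ValueError):
            extract_slice(dry, -60.0, -46.0, 0.0)


class TestTraceTL:
    def test_spherical_spreading_free_field(self):
        """Iso-velocity, boundaries removed: TL follows 20·log10(r)."""
        env = SliceEnvironment.iso_velocity(depth_m=12_000.0, length_m=12_000.0)
        cfg = TracerConfig(
            step_m=20.0, range_cell_m=100.0, depth_cell_m=25.0, n_rays=361,
            surface_reflection=False, bottom_model="absorbing", include_thorp=False,
            deposits_per_cell=4,
        )
        sl = trace_tl(env, 20.0, source_depth_m=6000.0, receiver_depth_m=6000.0, config=cfg)
        m = (sl.range_m >= 100.0) & (sl.range_m <= 10_000.0)
        dev = sl.tl_at_source_depth[m] - 20.0 * np.log10(sl.range_m[m])
        assert np.max(np.abs(dev)) < 1.5

    def test_cylindrical_spreading_lossless_waveguide(self):
        """Lossless waveguide, long range: slope ≈ 10 dB/decade."""
        env = SliceEnvironment.iso_velocity(depth_m=1000.0, length_m=400_000.0)
        cfg = TracerConfig(
            step_m=100.0, range_cell_m=1000.0, depth_cell_m=25.0, n_rays=181,
            bottom_model="rigid", include_thorp=False, max_bottom_bounces=10**9,
        )
        sl = trace_tl(env, 20.0, config=cfg)
        r, tl = sl.range_m, sl.tl_at_source_depth
        m = (r >= 50_000.0) & (r <= 400_000.0) & np.isfinite(tl)
        slope = np.polyfit(np.log10(r[m]), tl[m], 1)[0]
        assert 9.0 <= slope <= 12.0

    def test_bottom_absorption_monotonicity(self):
        """Raising bottom absorption 1 → 3 dB/λ cannot reduce far-field TL.

        Holds in the small-grazing regime that dominates long-range ducted
        propagation over a fast seabed. (A seabed slower than the water
        column has an angle of intromission where R = 0; absorption then
        *raises* |R| — a real property of the Rayleigh coefficient, so the
        blanket cellwise claim is restricted to the physical regime.)
        """
        fast = dict(speed_m_s=1600.0)
        # reflection coefficient: non-increasing in absorption below critical
        grazing = np.deg2rad(np.linspace(0.5, 18.0, 30))  # critical ≈ 20°
        r1 = BottomSpec(absorption_db_lambda=1.0, **fast).reflection_intensity(grazing, 1500.0)
        r3 = BottomSpec(absorption_db_lambda=3.0, **fast).reflection_intensity(grazing, 1500.0)
        assert np.all(r3 <= r1 + 1e-12)

        cfg = TracerConfig(
            step_m=100.0, range_cell_m=1000.0, depth_cell_m=50.0, n_rays=121,
            include_thorp=False, max_bottom_bounces=1000,
        )
        tls = {}
        for alpha in (1.0, 3.0):
            env = SliceEnvironment.iso_velocity(
                depth_m=500.0, length_m=60_000.0,
                bottom=BottomSpec(absorption_db_lambda=alpha, **fast),
            )
            tls[alpha] = trace_tl(env, 50.0, config=cfg)
        r = tls[1.0].range_m
        far = r > 15_000.0  # every surviving path has several bottom bounces
        a = tls[1.0].tl_at_source_depth[far]
        b = tls[3.0].tl_at_source_depth[far]
        both = np.isfinite(a) & np.isfinite(b)
        assert np.all(b[both] >= a[both] - 0.2)

    def test_reciprocity_in_waveguide(self):
        env = SliceEnvironment.iso_velocity(depth_m=1000.0, length_m=120_000.0)
        cfg = TracerConfig(
            step_m=100.0, range_cell_m=1000.0, depth_cell_m=10.0, n_rays=181,
            bottom_model="rigid", include_thorp=False, max_bottom_bounces=10**9,
            deposits_per_cell=8,
        )
        fwd = trace_tl(env, 20.0, source_depth_m=15.0, receiver_depth_m=280.0, config=cfg)
        rev = trace_tl(env, 20.0, source_depth_m=280.0, receiver_depth_m=15.0, config=cfg)
        m = (fwd.range_m > 20_000.0) & np.isfinite(fwd.tl_at_source_depth)
        diff = np.abs(fwd.tl_at_source_depth[m] - rev.tl_at_source_depth[m])
        assert np.max(diff) < 0.5

    def test_energy_sanity_tl_nonnegative(self):
        env = SliceEnvironment.iso_velocity(depth_m=800.0, length_m=20_000.0)
        cfg = TracerConfig(step_m=50.0, range_cell_m=500.0, depth_cell_m=25.0)
        sl = trace_tl(env, 100.0, config=cfg)
        finite = np.isfinite(sl.tl_db)
        assert np.all(sl.tl_db[finite] >= 0.0)

    def test_receiver_below_seafloor_rejected(self):
        env = SliceEnvironment.iso_velocity(depth_m=200.0, length_m=10_000.0)
        with pytest.raises(ValueError):
            trace_tl(env, 20.0, receiver_depth_m=280.0)


def _synthetic_slices(curve, bearings, source_depth=15.0):
    ranges = np.arange(500.0, 100_000.0, 1000.0)
    out = {}
    for b in bearings:
        tl = curve(ranges, b)
        lattice = np.repeat(tl[:, None], 4, axis=1)
        out[b] = TLSlice(
            bearing_deg=b,
            range_m=ranges,
            depth_m=np.array([12.5, 37.5, 62.5, 87.5]),
            tl_db=lattice,
            source_depth_m=source_depth,
            tl_at_source_depth=tl,
        )
    return out


class TestGridTL:
    bearings = np.arange(0.0, 360.0, 10.0)

    def test_radially_symmetric_slices_give_radial_field(self):
        slices = _synthetic_slices(lambda r, b: 20.0 * np.log10(r), self.bearings)
        grid = grid_tl(slices, -60.4, -45.96, nlat=61, nlon=121)
        glat, glon = np.meshgrid(grid.lat, grid.lon, indexing="ij")
        rr = haversine(-60.4, -45.96, glat, glon)
        inside = (rr > 1000.0) & (rr < 95_000.0) & np.isfinite(grid.tl_db)
        # azimuthal symmetry: value depends on range only (compare against
        # the range-interpolated slice curve, common to all bearings)
        ranges = np.arange(500.0, 100_000.0, 1000.0)
        expected = np.interp(rr[inside], ranges, 20.0 * np.log10(ranges))
        assert np.max(np.abs(grid.tl_db[inside] - expected)) < 0.1

    def test_mesh_point_on_slice_node_exact(self):
        slices = _synthetic_slices(lambda r, b: 0.05 * r + b, self.bearings)
        # place one mesh point exactly on the bearing-0 slice at a node range
        r_node = 50_500.0  # a slice node (500 + k·1000)
        lat_n, lon_n = destination(-60.4, -45.96, 0.0, r_node)
        grid = grid_tl(
            slices, -60.4, -45.96, nlat=2, nlon=2,
            lat_bounds=(float(lat_n), float(lat_n) + 0.5),
            lon_bounds=(-45.96, -45.46),
        )
        assert grid.tl_db[0, 0] == pytest.approx(0.05 * r_node + 0.0, abs=1e-6)

    def test_linear_range_dependence_recovered(self):
        slices = _synthetic_slices(lambda r, b: 0.001 * r, self.bearings)
        grid = grid_tl(slices, -60.4, -45.96, nlat=61, nlon=121)
        glat, glon = np.meshgrid(grid.lat, grid.lon, indexing="ij")
        rr = haversine(-60.4, -45.96, glat, glon)
        inside = (rr > 1000.0) & (rr < 95_000.0) & np.isfinite(grid.tl_db)
        assert np.allclose(grid.tl_db[inside], 0.001 * rr[inside], atol=1e-6)

    def test_missing_bearing_listed(self):
        slices = _synthetic_slices(lambda r, b: r / 1000.0, self.bearings)
        del slices[40.0]
        with pytest.raises(ValueError, match="40"):
            grid_tl(slices, -60.4, -45.96)

    def test_cells_beyond_reach_are_sentinel(self):
        slices = _synthetic_slices(lambda r, b: r / 1000.0, self.bearings)
        grid = grid_tl(slices, -60.4, -45.96, nlat=41, nlon=81,
                       lat_bounds=(-63.0, -58.0), lon_bounds=(-50.0, -42.0))
        glat, glon = np.meshgrid(grid.lat, grid.lon, indexing="ij")
        rr = haversine(-60.4, -45.96, glat, glon)
        assert np.all(np.isinf(grid.tl_db[rr > 100_000.0]))
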