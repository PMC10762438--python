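"""Range-dependent 2-D transmission loss along radial slices.

A simplified geometric ray tracer stands in for a full beam-tracing
propagation code. A fan of rays is launched from the recorder (source and
receiver are swapped by reciprocity), refracted by a piecewise-linear sound
speed profile per range segment, reflected specularly at the surface, and
reflected at the bottom with a Rayleigh-style fluid-fluid loss plus bottom
absorption expressed in dB per wavelength. Ray-tube intensity is
accumulated *incoherently* on a range × depth lattice; TL is
−10·log₁₀(intensity) relative to the 1 m free-field reference.

The incoherent summation reproduces the spreading-law limits that matter
for audible-area estimation — spherical (20 log r) in a free field and
cylindrical (10 log r) in a waveguide — but no interference structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import xarray as xr

from .geodesy import destination, haversine, initial_bearing


def sound_speed(temperature_c, salinity_psu, depth_m):
    """Sound speed in seawater (m/s), Mackenzie nine-term equation.

    Valid for T ∈ [−2, 30] °C, S ∈ [25, 40] psu, z ∈ [0, 8000] m; values
    outside are extrapolated (with the polynomial) rather than rejected.
    """
    t = np.asarray(temperature_c, dtype=float)
    s = np.asarray(salinity_psu, dtype=float)
    z = np.asarray(depth_m, dtype=float)
    return (
        1448.96
        + 4.591 * t
        - 5.304e-2 * t**2
        + 2.374e-4 * t**3
        + 1.340 * (s - 35.0)
        + 1.630e-2 * z
        + 1.675e-7 * z**2
        - 1.025e-2 * t * (s - 35.0)
        - 7.139e-13 * t * z**3
    )


def thorp_absorption_db_per_km(frequency_hz: float) -> float:
    """Thorp seawater volume absorption (dB/km); negligible below 200 Hz."""
    f2 = (frequency_hz / 1000.0) ** 2
    return 0.0033 + 0.11 * f2 / (1.0 + f2) + 44.0 * f2 / (4100.0 + f2) + 3.0e-4 * f2


@dataclass(frozen=True)
class BottomSpec:
    """Fluid half-space seabed: density, compressional speed, absorption.

    ``absorption_db_lambda`` is in dB per wavelength and enters the
    reflection coefficient through a complex bottom sound speed.
    """

    density_kg_m3: float = 1200.0
    speed_m_s: float = 1450.0
    absorption_db_lambda: float = 1.0

    def __post_init__(self):
        if min(self.density_kg_m3, self.speed_m_s) <= 0 or self.absorption_db_lambda < 0:
            raise ValueError("bottom parameters must be positive")

    def reflection_intensity(self, grazing_rad: np.ndarray, c_water: np.ndarray) -> np.ndarray:
        """|R|² for grazing angles (rad) at the water–bottom interface."""
        theta = np.clip(np.asarray(grazing_rad, dtype=float), 1e-4, np.pi / 2)
        # attenuation α dB/λ → loss tangent δ on the bottom wavenumber
        delta = self.absorption_db_lambda * np.log(10.0) / (40.0 * np.pi)
        c2 = self.speed_m_s / (1.0 + 1j * delta)
        rho1, rho2 = 1027.0, self.density_kg_m3
        cos_t2 = np.cos(theta) * c2 / c_water
        sin_t2 = np.sqrt(1.0 + 0j - cos_t2**2)
        z1 = rho1 * c_water / np.sin(theta)
        z2 = rho2 * c2 / sin_t2
        r = (z2 - z1) / (z2 + z1)
        return np.abs(r) ** 2


@dataclass
class TracerConfig:
    """Numerical knobs of the ray tracer."""

    n_rays: int = 181
    max_angle_deg: float = 80.0
    step_m: float = 100.0
    range_cell_m: float = 1000.0
    depth_cell_m: float = 25.0
    max_bottom_bounces: int = 20
    include_thorp: bool = True
    surface_reflection: bool = True
    bottom_model: str = "rayleigh"  # "rayleigh" | "rigid" | "absorbing"
    deposits_per_cell: int = 1  # >1 averages several range samples per cell


@dataclass
class SliceEnvironment:
    """One radial slice: bathymetry profile and sound-speed field c(range, z)."""

    bearing_deg: float
    ranges_m: np.ndarray  # ascending from 0
    depths_m: np.ndarray  # water depth per range node, > 0
    z_nodes_m: np.ndarray  # depth axis of the SSP
    c_m_s: np.ndarray  # (n_range_nodes, n_z) sound speed
    bottom: BottomSpec = field(default_factory=BottomSpec)

    def __post_init__(self):
        r = np.asarray(self.ranges_m, dtype=float)
        if r[0] != 0 or np.any(np.diff(r) <= 0):
            raise ValueError("ranges must ascend from 0")
        if np.any(np.asarray(self.depths_m) <= 0):
            raise ValueError("slice depths must be positive (land truncates the slice)")
        c = np.asarray(self.c_m_s, dtype=float)
        if c.min() < 1400.0 or c.max() > 1600.0:
            raise ValueError("sound speed outside plausible [1400, 1600] m/s")
        self.ranges_m = r
        self.depths_m = np.asarray(self.depths_m, dtype=float)
        self.z_nodes_m = np.asarray(self.z_nodes_m, dtype=float)
        self.c_m_s = c

    @classmethod
    def iso_velocity(
        cls,
        depth_m: float = 1000.0,
        length_m: float = 100_000.0,
        c: float = 1500.0,
        bearing_deg: float = 0.0,
        bottom: Optional[BottomSpec] = None,
    ) -> "SliceEnvironment":
        """Flat-bottom constant-sound-speed slice (test waveguides)."""
        ranges = np.array([0.0, length_m])
        z = np.array([0.0, depth_m])
        return cls(
            bearing_deg=bearing_deg,
            ranges_m=ranges,
            depths_m=np.full(2, depth_m),
            z_nodes_m=z,
            c_m_s=np.full((2, 2), c),
            bottom=bottom or BottomSpec(),
        )


@dataclass
class TLSlice:
    """TL (dB ≥ 0, +inf where no ray arrives) on a range × depth lattice."""

    bearing_deg: float
    range_m: np.ndarray  # cell centres
    depth_m: np.ndarray  # cell centres
    tl_db: np.ndarray  # (n_range, n_depth)
    source_depth_m: float
    tl_at_source_depth: np.ndarray  # (n_range,) TL curve at the source depth

    def tl_at_depth(self, z: float) -> np.ndarray:
        return self.tl_db[:, int(np.argmin(np.abs(self.depth_m - z)))]


def _profile_at(env: SliceEnvironment, r: float) -> tuple[np.ndarray, np.ndarray]:
    """Sound speed and dc/dz at the range node nearest r."""
    i = int(np.argmin(np.abs(env.ranges_m - r)))
    return env.z_nodes_m, env.c_m_s[i]


def trace_tl(
    env: SliceEnvironment,
    frequency_hz: float,
    source_depth_m: float = 15.0,
    receiver_depth_m: float = 280.0,
    config: Optional[TracerConfig] = None,
) -> TLSlice:
    """Trace the ray fan from the recorder and accumulate incoherent TL.

    By acoustic reciprocity the fan is launched from the *receiver* depth
    (the moored recorder); the returned ``tl_at_source_depth`` curve is the
    TL between the recorder and a shallow calling animal at
    ``source_depth_m``, per range.
    """
    cfg = config or TracerConfig()
    if receiver_depth_m >= env.depths_m[0]:
        raise ValueError("receiver depth must be above the sea floor at range 0")

    length = float(env.ranges_m[-1])
    r_edges = np.arange(0.0, length + cfg.range_cell_m, cfg.range_cell_m)
    r_centres = 0.5 * (r_edges[:-1] + r_edges[1:])
    max_depth = float(env.depths_m.max())
    dz = cfg.depth_cell_m
    z_edges = np.arange(0.0, max_depth + dz, dz)
    z_centres = 0.5 * (z_edges[:-1] + z_edges[1:])
    intensity = np.zeros((r_centres.size, z_centres.size))

    theta0 = np.deg2rad(
        np.linspace(-cfg.max_angle_deg, cfg.max_angle_deg, cfg.n_rays)
    )
    dtheta = theta0[1] - theta0[0]
    # per-pair launch flux: cosθ₀·Δθ₀ at the pair midpoint
    flux0 = np.cos(0.5 * (theta0[:-1] + theta0[1:])) * dtheta

    z = np.full(cfg.n_rays, float(receiver_depth_m))
    theta = theta0.copy()
    loss = np.ones(cfg.n_rays)  # linear intensity factor (bottom + volume)
    alive = np.ones(cfg.n_rays, dtype=bool)
    bounces = np.zeros(cfg.n_rays, dtype=int)
    refl = np.zeros(cfg.n_rays, dtype=int)  # total boundary reflections
    last_boundary = np.zeros(cfg.n_rays, dtype=int)  # 0 surface, 1 bottom

    alpha_m = thorp_absorption_db_per_km(frequency_hz) / 1000.0 if cfg.include_thorp else 0.0
    dr = cfg.step_m
    n_steps = int(np.ceil(length / dr))
    # bathymetry slope per step, for specular reflection off a sloping bottom
    r_fine = np.arange(n_steps + 1) * dr
    d_fine = np.interp(r_fine, env.ranges_m, env.depths_m)
    slope_fine = np.gradient(d_fine, dr)

    # deposits_per_cell range samples per output cell, averaged
    deposit_col = {}
    n_dep = np.zeros(r_centres.size)
    k_dep = max(1, cfg.deposits_per_cell)
    for c in range(r_centres.size):
        for q in range(k_dep):
            r_target = r_edges[c] + (q + 0.5) / k_dep * cfg.range_cell_m
            step_idx = min(n_steps - 1, max(0, int(round(r_target / dr)) - 1))
            if step_idx not in deposit_col:
                deposit_col[step_idx] = c
                n_dep[c] += 1

    for i in range(n_steps):
        r0, r1 = i * dr, (i + 1) * dr
        z_nodes, c_prof = _profile_at(env, 0.5 * (r0 + r1))
        c_here = np.interp(z, z_nodes, c_prof)
        snell = np.cos(theta) / c_here

        z_new = z + np.tan(theta) * dr
        c_new = np.interp(np.clip(z_new, 0.0, z_nodes[-1]), z_nodes, c_prof)
        cos_new = snell * c_new
        turning = cos_new >= 1.0
        # refraction turning point: do not advance in depth, flip direction
        z_new = np.where(turning, z, z_new)
        sign = np.where(theta >= 0, 1.0, -1.0)
        theta = np.where(
            turning, -theta, sign * np.arccos(np.clip(cos_new, -1.0, 1.0))
        )

        # surface
        hit_surface = z_new < 0.0
        if cfg.surface_reflection:
            z_new = np.where(hit_surface, -z_new, z_new)
            theta = np.where(hit_surface, -theta, theta)
            refl = refl + hit_surface.astype(int)
            last_boundary = np.where(hit_surface, 0, last_boundary)
        else:
            alive &= ~hit_surface

        # bottom
        d_here = d_fine[i + 1]
        hit_bottom = z_new > d_here
        if np.any(hit_bottom & alive):
            beta = np.arctan(slope_fine[i + 1])
            grazing = np.abs(theta) - beta * np.sign(theta)
            grazing = np.clip(np.abs(grazing), 1e-3, np.pi / 2)
            if cfg.bottom_model == "rigid":
                r_coef = np.ones_like(z_new)
            elif cfg.bottom_model == "absorbing":
                r_coef = np.zeros_like(z_new)
            else:
                r_coef = env.bottom.reflection_intensity(
                    grazing, np.interp(d_here, z_nodes, c_prof)
                )
            loss = np.where(hit_bottom, loss * r_coef, loss)
            z_new = np.where(hit_bottom, 2.0 * d_here - z_new, z_new)
            theta = np.where(hit_bottom, -theta + 2.0 * beta, theta)
            bounces = bounces + hit_bottom.astype(int)
            refl = refl + hit_bottom.astype(int)
            last_boundary = np.where(hit_bottom, 1, last_boundary)
            alive &= bounces <= cfg.max_bottom_bounces
            alive &= loss > 1e-20

        if alpha_m > 0:
            path = dr / np.clip(np.cos(theta), 0.3, 1.0)
            loss = loss * 10.0 ** (-alpha_m * path / 10.0)

        z = z_new

        col = deposit_col.get(i)
        if col is not None:
            _deposit(
                intensity[col],
                z,
                theta,
                loss,
                alive,
                flux0,
                max(r1, 1.0),
                z_edges,
                min(d_here, z_edges[-1]),
                refl,
                last_boundary,
            )

    intensity /= np.maximum(n_dep, 1)[:, None]
    with np.errstate(divide="ignore"):
        tl = -10.0 * np.log10(intensity)
    tl = np.where(np.isfinite(tl), np.maximum(tl, 0.0), np.inf)
    # mask sub-bottom cells as sentinel
    d_cells = np.interp(r_centres, env.ranges_m, env.depths_m)
    tl[z_centres[None, :] > d_cells[:, None]] = np.inf

    src_idx = int(np.argmin(np.abs(z_centres - source_depth_m)))
    return TLSlice(
        bearing_deg=env.bearing_deg,
        range_m=r_centres,
        depth_m=z_centres,
        tl_db=tl,
        source_depth_m=source_depth_m,
        tl_at_source_depth=tl[:, src_idx].copy(),
    )


def _add_segment(column, z_edges, z_lo, z_hi, intensity_val):
    """Add intensity of a tube segment [z_lo, z_hi] as cell averages."""
    dz = z_edges[1] - z_edges[0]
    a = int(np.clip(np.searchsorted(z_edges, z_lo, side="right") - 1, 0, column.size - 1))
    b = int(np.clip(np.searchsorted(z_edges, z_hi, side="right") - 1, 0, column.size - 1))
    if a == b:
        column[a] += intensity_val * (z_hi - z_lo) / dz
        return
    column[a] += intensity_val * (z_edges[a + 1] - z_lo) / dz
    column[b] += intensity_val * (z_hi - z_edges[b]) / dz
    if b > a + 1:
        column[a + 1 : b] += intensity_val


def _deposit(column, z, theta, loss, alive, flux0, r, z_edges, bottom_depth, refl, last_boundary):
    """Add cell-averaged ray-tube intensity of adjacent-ray pairs to a column.

    A tube between adjacent launch angles carries flux cosθ₀Δθ₀; its
    intensity at range r is flux·loss/(r·Δz·cosθ). Depositing cell averages
    keeps caustics (Δz → 0) finite at lattice resolution. Pairs that
    straddle a boundary reflection (unequal reflection counts) are folded:
    the tube is split into two image sub-tubes meeting at the boundary, so
    near-surface and near-bottom cells receive their full share of energy.
    Pairs that folded more than once between deposits are spread uniformly
    over the water column (their energy is depth-mixed at this resolution).
    """
    ok = alive[:-1] & alive[1:]
    if not np.any(ok):
        return
    idx = np.flatnonzero(ok)
    zi = np.clip(z[idx], 0.0, bottom_depth)
    zj = np.clip(z[idx + 1], 0.0, bottom_depth)
    cos_mid = np.clip(np.cos(0.5 * (theta[idx] + theta[idx + 1])), 0.17, 1.0)
    loss_mid = 0.5 * (loss[idx] + loss[idx + 1])
    flux = flux0[idx] * loss_mid / (r * cos_mid)
    dref = np.abs(refl[idx] - refl[idx + 1])

    for k in range(idx.size):
        if dref[k] == 0:
            lo, hi = (zi[k], zj[k]) if zi[k] <= zj[k] else (zj[k], zi[k])
            span = max(hi - lo, 1e-6)
            _add_segment(column, z_edges, lo, hi, flux[k] / span)
        elif dref[k] == 1:
            # folded once: the more-recently reflected ray marks the boundary
            recent = idx[k] if refl[idx[k]] > refl[idx[k] + 1] else idx[k] + 1
            if last_boundary[recent] == 0:  # surface fold
                span = max(zi[k] + zj[k], 1e-6)
                val = flux[k] / span
                _add_segment(column, z_edges, 0.0, max(zi[k], 1e-9), val)
                _add_segment(column, z_edges, 0.0, max(zj[k], 1e-9), val)
            else:  # bottom fold
                span = max(2.0 * bottom_depth - zi[k] - zj[k], 1e-6)
                val = flux[k] / span
                _add_segment(column, z_edges, min(zi[k], bottom_depth - 1e-9), bottom_depth, val)
                _add_segment(column, z_edges, min(zj[k], bottom_depth - 1e-9), bottom_depth, val)
        else:
            # multiply folded between deposits: depth-mixed
            _add_segment(column, z_edges, 0.0, bottom_depth, flux[k] / bottom_depth)


def extract_slice(
    bathymetry: xr.DataArray,
    origin_lat: float,
    origin_lon: float,
    bearing_deg: float,
    *,
    length_m: float = 500_000.0,
    range_step_m: float = 5000.0,
    sst: Optional[xr.DataArray] = None,
    salinity_psu: float = 34.2,
    deep_temperature_c: float = 0.5,
    thermocline_scale_m: float = 100.0,
    bottom: Optional[BottomSpec] = None,
) -> SliceEnvironment:
    """Sample bathymetry and sound speed along a great-circle bearing.

    The water column temperature profile is built from the (optionally
    time-averaged) surface temperature decaying exponentially to
    ``deep_temperature_c`` over ``thermocline_scale_m``, with constant
    salinity; sound speed follows the Mackenzie equation. Land (depth ≤ 0)
    truncates the slice at the first dry node.
    """
    d0 = float(bathymetry.interp(lat=origin_lat, lon=origin_lon).values)
    if not np.isfinite(d0) or d0 <= 0:
        raise ValueError("slice origin lies on land")
    ranges = np.arange(0.0, length_m + range_step_m, range_step_m)
    lats, lons = destination(origin_lat, origin_lon, bearing_deg, ranges)
    depths = bathymetry.interp(
        lat=xr.DataArray(lats, dims="r"), lon=xr.DataArray(lons, dims="r")
    ).values.astype(float)
    depths = np.where(np.isfinite(depths), depths, 0.0)
    dry = np.flatnonzero(depths <= 0.0)
    if dry.size and dry[0] == 0:
        raise ValueError("slice origin lies on land")
    if dry.size:
        ranges, depths, lats, lons = (
            a[: dry[0]] for a in (ranges, depths, lats, lons)
        )

    if sst is not None:
        field2d = sst.mean("time") if "time" in sst.dims else sst
        surf_t = field2d.interp(
            lat=xr.DataArray(lats, dims="r"), lon=xr.DataArray(lons, dims="r")
        ).values.astype(float)
        surf_t = np.where(np.isfinite(surf_t), surf_t, deep_temperature_c)
    else:
        surf_t = np.full(ranges.size, deep_temperature_c)

    z_nodes = np.concatenate([np.arange(0.0, 300.0, 25.0), np.arange(300.0, 5001.0, 100.0)])
    t_rz = deep_temperature_c + (surf_t[:, None] - deep_temperature_c) * np.exp(
        -z_nodes[None, :] / thermocline_scale_m
    )
    c = sound_speed(t_rz, salinity_psu, z_nodes[None, :])
    return SliceEnvironment(
        bearing_deg=bearing_deg,
        ranges_m=ranges,
        depths_m=depths,
        z_nodes_m=z_nodes,
        c_m_s=c,
        bottom=bottom or BottomSpec(),
    )


@dataclass
class TLGrid:
    """Transmission loss gridded onto a lat/lon mesh for one frequency."""

    lat: np.ndarray
    lon: np.ndarray
    tl_db: np.ndarray  # (nlat, nlon), +inf sentinel beyond coverage/on land
    frequency_hz: float
    origin_lat: float
    origin_lon: float

    def to_dataarray(self) -> xr.DataArray:
        return xr.DataArray(
            self.tl_db,
            coords={"lat": self.lat, "lon": self.lon},
            dims=("lat", "lon"),
            name="tl_db",
            attrs={"frequency_hz": self.frequency_hz},
        )

    def to_netcdf(self, path) -> None:
        da = self.to_dataarray()
        da.where(np.isfinite(da)).to_netcdf(path, engine="scipy")


def grid_tl(
    slices: dict[float, TLSlice],
    origin_lat: float,
    origin_lon: float,
    *,
    nlat: int = 218,
    nlon: int = 464,
    lat_bounds: Optional[tuple[float, float]] = None,
    lon_bounds: Optional[tuple[float, float]] = None,
    frequency_hz: float = 0.0,
    bathymetry: Optional[xr.DataArray] = None,
) -> TLGrid:
    """Linear interpolation of per-bearing TL curves onto a lat/lon mesh.

    ``slices`` maps bearing (deg, a complete uniform circle) to TLSlice;
    interpolation is bilinear in polar (bearing, range) coordinates with
    periodic bearing wrap. Mesh cells beyond the slice length or on land
    carry the +inf sentinel.
    """
    bearings = np.array(sorted(slices))
    if bearings.size < 2:
        raise ValueError("need at least two bearings")
    step = float(np.median(np.diff(bearings)))
    expected = np.arange(0.0, 360.0 - 1e-9, step)
    if not (bearings.size == expected.size and np.allclose(bearings, expected, atol=1e-6)):
        missing = sorted(set(np.round(expected, 6)) - set(np.round(bearings, 6)))
        raise ValueError(
            "bearings must uniformly cover the circle; missing "
            + ", ".join(f"{m:g}" for m in missing[:10])
        )

    ranges = slices[bearings[0]].range_m
    curves = np.stack([slices[b].tl_at_source_depth for b in bearings])  # (nb, nr)
    # pad for periodic bearing interpolation
    curves_p = np.vstack([curves, curves[:1]])
    bearings_p = np.append(bearings, 360.0)

    if lat_bounds is None or lon_bounds is None:
        reach = ranges[-1] + (ranges[1] - ranges[0])
        dlat = np.rad2deg(reach / 6_371_000.0)
        dlon = dlat / np.cos(np.deg2rad(origin_lat))
        lat_bounds = lat_bounds or (origin_lat - dlat, origin_lat + dlat)
        lon_bounds = lon_bounds or (origin_lon - dlon, origin_lon + dlon)
    lat = np.linspace(lat_bounds[0], lat_bounds[1], nlat)
    lon = np.linspace(lon_bounds[0], lon_bounds[1], nlon)
    glat, glon = np.meshgrid(lat, lon, indexing="ij")
    rng = haversine(origin_lat, origin_lon, glat, glon)
    brg = initial_bearing(origin_lat, origin_lon, glat, glon)

    from scipy.interpolate import RegularGridInterpolator

    finite = np.where(np.isfinite(curves_p), curves_p, np.nan)
    interp = RegularGridInterpolator(
        (bearings_p, ranges), finite, bounds_error=False, fill_value=np.nan
    )
    tl = interp(np.stack([brg.ravel(), np.clip(rng.ravel(), ranges[0], ranges[-1])], axis=1))
    tl = tl.reshape(glat.shape)
    tl[rng > ranges[-1]] = np.nan
    if bathymetry is not None:
        depth = bathymetry.interp(
            lat=xr.DataArray(lat, dims="lat"), lon=xr.DataArray(lon, dims="lon")
        ).values
        tl[~(depth > 0)] = np.nan
    tl = np.where(np.isfinite(tl), tl, np.inf)
    return TLGrid(
        lat=lat,
        lon=lon,
        tl_db=tl,
        frequency_hz=frequency_hz,
        origin_lat=origin_lat,
        origin_lon=origin_lon,
    )
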