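"""Audible-area masks and ice-constrained environmental covariates.

The audible area of a recorder for a calling species is the region where
SNR = SL − TL − NL exceeds 5 dB, with SL the species' source level, TL the
modelled transmission loss to the recorder and NL the measured noise level
at the call frequency. Daily audible masks spatially constrain the
environmental covariates entering the community statistics: the proportion
of the audible area under sea ice (SIC > 30%), the mean SST/SSH over the
ice-free audible cells, and the coefficient of variation of depth (vBAT)
there — a proxy for how much of the heterogeneous shelf remains accessible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import xarray as xr

from .geodesy import cell_areas_km2, haversine
from .raytrace import TLGrid

SNR_THRESHOLD_DB = 5.0
SIC_ICE_THRESHOLD_PCT = 30.0


@dataclass(frozen=True)
class SpeciesAcousticSpec:
    """Call frequency and source level used for audible-area modelling."""

    species: str
    frequency_hz: float
    source_level_db: float
    guild: str = ""

    def __post_init__(self):
        if self.frequency_hz <= 0:
            raise ValueError("frequency must be positive")
        if not 120.0 <= self.source_level_db <= 220.0:
            raise ValueError("source level outside plausible [120, 220] dB re 1 µPa")


# Source levels and frequencies used for the four modelled baleen whales.
TABLE_SPECIES = (
    SpeciesAcousticSpec("FW", 20.0, 189.0, "ice-avoiding"),
    SpeciesAcousticSpec("ABW", 20.0, 189.0, "resident"),
    SpeciesAcousticSpec("AMW", 100.0, 163.0, "ice-affiliated"),
    SpeciesAcousticSpec("HW", 200.0, 163.0, "ice-avoiding"),
)


def snr_grid(tl: TLGrid, source_level_db: float, noise_level_db: float) -> xr.DataArray:
    """SNR = SL − TL − NL elementwise; −inf where TL carries the sentinel."""
    tl_da = tl.to_dataarray()
    snr = source_level_db - tl_da - noise_level_db
    return snr.rename("snr_db")


@dataclass
class AudibleMask:
    """Boolean audible-area grid and its latitude-weighted area."""

    mask: xr.DataArray  # bool (lat, lon)
    area_km2: float
    date: Optional[pd.Timestamp] = None
    species: str = ""
    frequency_hz: float = 0.0
    occupancy: Optional[xr.DataArray] = None  # continuous mean, for daily masks

    def to_netcdf(self, path) -> None:
        self.mask.astype(np.int8).rename("audible").to_netcdf(path, engine="scipy")

    def to_geojson(self, path) -> None:
        """Write the mask outline as a GeoJSON MultiPolygon of cell boxes."""
        import json

        from shapely.geometry import box, mapping
        from shapely.ops import unary_union

        lat = self.mask.lat.values
        lon = self.mask.lon.values
        dla = abs(lat[1] - lat[0]) / 2.0
        dlo = abs(lon[1] - lon[0]) / 2.0
        cells = [
            box(lon[j] - dlo, lat[i] - dla, lon[j] + dlo, lat[i] + dla)
            for i, j in zip(*np.nonzero(self.mask.values))
        ]
        geom = unary_union(cells) if cells else None
        feature = {
            "type": "Feature",
            "properties": {"species": self.species, "area_km2": self.area_km2},
            "geometry": mapping(geom) if geom is not None else None,
        }
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": [feature]}, fh)


def _mask_area(mask: np.ndarray, lat: np.ndarray, lon: np.ndarray) -> float:
    return float(cell_areas_km2(lat, lon)[mask].sum())


def audible_mask(
    snr: xr.DataArray,
    *,
    threshold_db: float = SNR_THRESHOLD_DB,
    date=None,
    species: str = "",
    frequency_hz: float = 0.0,
) -> AudibleMask:
    """Cells strictly above the SNR threshold, with latitude-weighted area."""
    if not np.isfinite(threshold_db):
        raise ValueError("threshold must be finite")
    vals = np.where(np.isfinite(snr.values), snr.values, -np.inf)
    m = vals > threshold_db
    mask = xr.DataArray(m, coords=snr.coords, dims=snr.dims, name="audible")
    return AudibleMask(
        mask=mask,
        area_km2=_mask_area(m, snr.lat.values, snr.lon.values),
        date=pd.Timestamp(date) if date is not None else None,
        species=species,
        frequency_hz=frequency_hz,
    )


def daily_mask(recording_masks: list[AudibleMask], *, occupancy_threshold: float = 0.5) -> AudibleMask:
    """Average per-recording masks into one daily mask.

    A cell is audible on the day iff it was audible in at least
    ``occupancy_threshold`` of the day's recordings (≥, so 12 of 24 counts).
    The continuous occupancy fraction is retained alongside.
    """
    if not recording_masks:
        raise ValueError("need at least one recording mask")
    stack = np.stack([m.mask.values for m in recording_masks]).astype(float)
    occ = stack.mean(axis=0)
    m = occ >= occupancy_threshold
    ref = recording_masks[0].mask
    mask = xr.DataArray(m, coords=ref.coords, dims=ref.dims, name="audible")
    return AudibleMask(
        mask=mask,
        area_km2=_mask_area(m, ref.lat.values, ref.lon.values),
        date=recording_masks[0].date,
        species=recording_masks[0].species,
        frequency_hz=recording_masks[0].frequency_hz,
        occupancy=xr.DataArray(occ, coords=ref.coords, dims=ref.dims, name="occupancy"),
    )


def _coregister(grid: xr.DataArray, like: xr.DataArray, method: str = "nearest") -> np.ndarray:
    """Resample a grid onto the mask mesh (nearest-neighbour by default)."""
    if grid.shape == like.shape and np.allclose(grid.lat, like.lat) and np.allclose(
        grid.lon, like.lon
    ):
        return grid.values
    return grid.interp(lat=like.lat, lon=like.lon, method=method).values


def sic_proportion(mask: AudibleMask, sic_pct: xr.DataArray) -> float:
    """Area proportion (0–1) of the audible area that is ice-covered.

    A cell counts as ice-covered iff SIC > 30%; below-threshold ice counts
    as ice-free. Returns NaN for an empty mask.
    """
    m = mask.mask.values
    if not m.any():
        return float("nan")
    sic = _coregister(sic_pct, mask.mask)
    areas = cell_areas_km2(mask.mask.lat.values, mask.mask.lon.values)
    icy = m & (sic > SIC_ICE_THRESHOLD_PCT)
    return float(areas[icy].sum() / areas[m].sum())


@dataclass
class ConstrainedCovariates:
    """Daily covariates constrained to the ice-free audible area."""

    date: Optional[pd.Timestamp]
    species: str
    frequency_hz: float
    sic_prop: float
    sst_mean: float
    ssh_mean: float
    vbat: float
    area_km2: float
    sic25_pct: float = float("nan")
    sic100_pct: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "date": self.date,
            "species": self.species,
            "frequency_hz": self.frequency_hz,
            "SIC_prop": self.sic_prop,
            "SST_mean": self.sst_mean,
            "SSH_mean": self.ssh_mean,
            "vBAT": self.vbat,
            "area_km2": self.area_km2,
            "SIC25": self.sic25_pct,
            "SIC100": self.sic100_pct,
        }


def constrained_stats(
    mask: AudibleMask,
    sic_pct: xr.DataArray,
    sst: xr.DataArray,
    ssh: xr.DataArray,
    bathymetry: xr.DataArray,
) -> ConstrainedCovariates:
    """Covariate statistics over audible, ice-free (SIC ≤ 30%) cells.

    Ice-covered cells are treated as missing (the calling animals are
    assumed outside heavy ice); vBAT is the population coefficient of
    variation sd(depth)/mean(depth) of the eligible cells. All-NA covariates
    are returned when no cell is eligible.
    """
    m = mask.mask.values
    sic = _coregister(sic_pct, mask.mask)
    eligible = m & ~(sic > SIC_ICE_THRESHOLD_PCT)
    prop = sic_proportion(mask, sic_pct)
    if not eligible.any():
        nan = float("nan")
        return ConstrainedCovariates(
            mask.date, mask.species, mask.frequency_hz, prop, nan, nan, nan, mask.area_km2
        )
    sst_v = _coregister(sst, mask.mask)[eligible]
    ssh_v = _coregister(ssh, mask.mask)[eligible]
    dep_v = _coregister(bathymetry, mask.mask)[eligible]
    vbat = float(np.std(dep_v) / np.mean(dep_v)) if np.mean(dep_v) != 0 else float("nan")
    return ConstrainedCovariates(
        date=mask.date,
        species=mask.species,
        frequency_hz=mask.frequency_hz,
        sic_prop=prop,
        sst_mean=float(np.nanmean(sst_v)),
        ssh_mean=float(np.nanmean(ssh_v)),
        vbat=vbat,
        area_km2=mask.area_km2,
    )


def radius_sic(
    sic_pct: xr.DataArray, center_lat: float, center_lon: float, radius_km: float
) -> float:
    """Area-weighted mean SIC (%) within a geodesic radius of the recorder."""
    lat = sic_pct.lat.values
    lon = sic_pct.lon.values
    glat, glon = np.meshgrid(lat, lon, indexing="ij")
    inside = haversine(center_lat, center_lon, glat, glon) <= radius_km * 1000.0
    if not inside.any():
        return float("nan")
    areas = cell_areas_km2(lat, lon)
    vals = sic_pct.values
    return float(np.sum(vals[inside] * areas[inside]) / np.sum(areas[inside]))


def covariate_table(covs: list[ConstrainedCovariates]) -> pd.DataFrame:
    """Tidy daily covariate CSV layout (one row per date × species)."""
    return pd.DataFrame([c.to_dict() for c in covs])
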