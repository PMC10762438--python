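"""Great-circle geometry on a spherical Earth.

All distances are in metres, angles in degrees. Bearings are measured
clockwise from true north. The sphere radius (6371 km, the mean Earth
radius) is the package-wide convention; at the ~500 km scales of audible
area estimation the difference from an ellipsoidal model is well below the
resolution of the transmission-loss mesh.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_M = 6_371_000.0


def destination(lat: float, lon: float, bearing_deg, distance_m):
    """Forward great-circle problem.

    Point(s) reached from (lat, lon) travelling ``distance_m`` along the
    initial bearing ``bearing_deg``. Accepts scalars or arrays (broadcast
    together); returns (lat, lon) in degrees with lon wrapped to [-180, 180).
    """
    phi1 = np.deg2rad(lat)
    lam1 = np.deg2rad(lon)
    theta = np.deg2rad(np.asarray(bearing_deg, dtype=float))
    delta = np.asarray(distance_m, dtype=float) / EARTH_RADIUS_M

    sin_phi2 = np.sin(phi1) * np.cos(delta) + np.cos(phi1) * np.sin(delta) * np.cos(theta)
    phi2 = np.arcsin(np.clip(sin_phi2, -1.0, 1.0))
    lam2 = lam1 + np.arctan2(
        np.sin(theta) * np.sin(delta) * np.cos(phi1),
        np.cos(delta) - np.sin(phi1) * sin_phi2,
    )
    lon2 = (np.rad2deg(lam2) + 180.0) % 360.0 - 180.0
    return np.rad2deg(phi2), lon2


def haversine(lat1, lon1, lat2, lon2):
    """Great-circle distance in metres between points in degrees."""
    phi1, phi2 = np.deg2rad(lat1), np.deg2rad(lat2)
    dphi = phi2 - phi1
    dlam = np.deg2rad(np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float))
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def initial_bearing(lat1, lon1, lat2, lon2):
    """Initial great-circle bearing (deg clockwise from north) from 1 to 2."""
    phi1, phi2 = np.deg2rad(lat1), np.deg2rad(lat2)
    dlam = np.deg2rad(np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float))
    y = np.sin(dlam) * np.cos(phi2)
    x = np.cos(phi1) * np.sin(phi2) - np.sin(phi1) * np.cos(phi2) * np.cos(dlam)
    return np.rad2deg(np.arctan2(y, x)) % 360.0


def cell_areas_km2(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Area (km²) of lat/lon grid cells centred on the given 1-D axes.

    Cells are cell-centred; widths are taken from axis spacing (uniform
    spacing assumed). Returns a (nlat, nlon) array: R²·Δλ·Δφ·cos(φ).
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if lat.size < 2 or lon.size < 2:
        raise ValueError("need at least 2 points per axis to infer cell size")
    dphi = np.deg2rad(abs(lat[1] - lat[0]))
    dlam = np.deg2rad(abs(lon[1] - lon[0]))
    r_km = EARTH_RADIUS_M / 1000.0
    band = r_km**2 * dphi * dlam * np.cos(np.deg2rad(lat))
    return np.repeat(band[:, None], lon.size, axis=1)
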