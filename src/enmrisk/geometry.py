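"""Spherical geometry helpers: great-circle distance and an equal-area projection.

All computations use a spherical earth of radius 6371 km. The projection is the
Lambert azimuthal equal-area projection, which preserves areas exactly on the
sphere and is therefore suitable for the extent-of-occurrence and
area-of-occupancy calculations used in IUCN Red List assessments.
"""
from __future__ import annotations

import numpy as np
from shapely.geometry.base import BaseGeometry
from shapely.ops import transform as shapely_transform

EARTH_RADIUS_KM = 6371.0


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km between points given in decimal degrees.

    Accepts scalars or broadcastable arrays.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float))
                              for v in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def pairwise_haversine_km(lonlat: np.ndarray) -> np.ndarray:
    """Symmetric matrix of great-circle distances for an (n, 2) lon/lat array."""
    lonlat = np.asarray(lonlat, dtype=float)
    lon = lonlat[:, 0]
    lat = lonlat[:, 1]
    return haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])


class AzimuthalEqualArea:
    """Spherical Lambert azimuthal equal-area projection centred on (lon0, lat0).

    Forward maps decimal degrees to planar kilometres; areas of projected
    geometries are true sphere areas (in km^2) up to the distortion of
    straight-line (chord) edges, which is negligible at the sub-continental
    scales this package works at.
    """

    def __init__(self, lon0: float, lat0: float, radius_km: float = EARTH_RADIUS_KM):
        self.lon0 = float(lon0)
        self.lat0 = float(lat0)
        self.radius_km = float(radius_km)

    def forward(self, lon, lat):
        lam = np.radians(np.asarray(lon, dtype=float)) - np.radians(self.lon0)
        phi = np.radians(np.asarray(lat, dtype=float))
        phi0 = np.radians(self.lat0)
        cosc = np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam)
        # antipodal point maps to infinity; clamp just inside
        denom = np.clip(1.0 + cosc, 1e-12, None)
        k = np.sqrt(2.0 / denom)
        x = self.radius_km * k * np.cos(phi) * np.sin(lam)
        y = self.radius_km * k * (np.cos(phi0) * np.sin(phi)
                                  - np.sin(phi0) * np.cos(phi) * np.cos(lam))
        return x, y

    def inverse(self, x, y):
        x = np.asarray(x, dtype=float) / self.radius_km
        y = np.asarray(y, dtype=float) / self.radius_km
        rho = np.sqrt(x ** 2 + y ** 2)
        c = 2.0 * np.arcsin(np.clip(rho / 2.0, -1.0, 1.0))
        phi0 = np.radians(self.lat0)
        with np.errstate(invalid="ignore", divide="ignore"):
            phi = np.where(
                rho == 0.0,
                phi0,
                np.arcsin(np.clip(np.cos(c) * np.sin(phi0)
                                  + y * np.sin(c) * np.cos(phi0) / np.where(rho == 0, 1, rho),
                                  -1.0, 1.0)),
            )
            lam = np.where(
                rho == 0.0,
                0.0,
                np.arctan2(x * np.sin(c),
                           rho * np.cos(phi0) * np.cos(c) - y * np.sin(phi0) * np.sin(c)),
            )
        return np.degrees(lam) + self.lon0, np.degrees(phi)

    def project_geometry(self, geom: BaseGeometry) -> BaseGeometry:
        return shapely_transform(lambda lon, lat: self.forward(lon, lat), geom)

    def unproject_geometry(self, geom: BaseGeometry) -> BaseGeometry:
        return shapely_transform(lambda x, y: self.inverse(x, y), geom)
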