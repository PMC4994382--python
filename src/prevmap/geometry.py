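"""Distance and local-projection helpers on the WGS84 sphere.

All public distances are kilometres.  A spherical earth of mean radius
6371.0088 km is used throughout; at the <= 5 km displacement scales and
near-equatorial latitudes this package targets, the error against a full
ellipsoid model is negligible relative to survey-cluster displacement.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088
KM_PER_DEG_LAT = EARTH_RADIUS_KM * np.pi / 180.0  # ~111.195


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points in decimal degrees.

    Accepts scalars or broadcastable numpy arrays.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def pairwise_haversine_km(lon, lat):
    """Full distance matrix (km) for vectors of lon/lat degrees."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    return haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])


def km_offset_to_lonlat(lon, lat, dx_km, dy_km):
    """Move a point by planar (east, north) km using a local flat-earth frame.

    Longitude km are scaled by cos(latitude) of the anchor point.  Adequate
    for offsets of a few km away from the poles.
    """
    lat2 = lat + dy_km / KM_PER_DEG_LAT
    lon2 = lon + dx_km / (KM_PER_DEG_LAT * np.cos(np.radians(lat)))
    return lon2, lat2


def lonlat_to_km_frame(lon, lat, lon0, lat0):
    """Project lon/lat degrees to planar (x, y) km about (lon0, lat0)."""
    x = (np.asarray(lon, dtype=float) - lon0) * KM_PER_DEG_LAT * np.cos(np.radians(lat0))
    y = (np.asarray(lat, dtype=float) - lat0) * KM_PER_DEG_LAT
    return x, y
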