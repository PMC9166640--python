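"""Great-circle geometry on WGS84 coordinates (spherical approximation)."""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088  # IUGG mean Earth radius


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between points given in decimal degrees.

    Accepts scalars or numpy arrays (broadcasting applies).
    """
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def haversine_m(lat1, lon1, lat2, lon2):
    return haversine_km(lat1, lon1, lat2, lon2) * 1000.0


def offset_latlon(lat, lon, east_km, north_km):
    """Displace (lat, lon) by local east/north offsets in km.

    Uses the local-tangent-plane approximation; adequate for the tens of km
    the cohort generator needs.
    """
    lat = np.asarray(lat, dtype=float)
    dlat = np.asarray(north_km, dtype=float) / EARTH_RADIUS_KM
    dlon = np.asarray(east_km, dtype=float) / (EARTH_RADIUS_KM * np.cos(np.radians(lat)))
    return lat + np.degrees(dlat), np.asarray(lon, dtype=float) + np.degrees(dlon)
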