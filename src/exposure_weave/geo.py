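"""Great-circle geometry helpers used throughout the package.

All distances are statute miles on a spherical Earth of radius 3958.8 mi,
the convention used for every trajectory and monitor-assignment computation.
"""
from __future__ import annotations

import numpy as np

EARTH_RADIUS_MI = 3958.8


def haversine_miles(lat1, lon1, lat2, lon2):
    """Great-circle distance between WGS84 points, in statute miles.

    Accepts scalars or broadcastable arrays of degrees.
    """
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return EARTH_RADIUS_MI * 2.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def path_length_miles(lats, lons) -> float:
    """Summed consecutive-fix great-circle distance of a trajectory (miles).

    A single fix (or empty input) has path length 0.
    """
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    if lats.size < 2:
        return 0.0
    return float(np.sum(haversine_miles(lats[:-1], lons[:-1], lats[1:], lons[1:])))


def destination_point(lat, lon, bearing_deg, distance_mi):
    """Point reached travelling ``distance_mi`` along ``bearing_deg`` from (lat, lon)."""
    lat1 = np.radians(lat)
    lon1 = np.radians(lon)
    brg = np.radians(bearing_deg)
    d = distance_mi / EARTH_RADIUS_MI
    lat2 = np.arcsin(np.sin(lat1) * np.cos(d) + np.cos(lat1) * np.sin(d) * np.cos(brg))
    lon2 = lon1 + np.arctan2(
        np.sin(brg) * np.sin(d) * np.cos(lat1),
        np.cos(d) - np.sin(lat1) * np.sin(lat2),
    )
    return np.degrees(lat2), np.degrees(lon2)
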