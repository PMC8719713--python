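"""Spherical geodesy primitives shared by every pipeline stage.

All distances are great-circle (haversine) distances on a sphere of mean
Earth radius 6371.0088 km, the convention used throughout the package for
displacement thresholds, path lengths and site linkage.  Coordinates are
unprojected WGS84 decimal degrees; longitudes are normalized to (-180, 180].

A local azimuthal-equidistant projection (``aeq_forward`` / ``aeq_inverse``)
provides the planar working frame for the correlated-random-walk model:
distances *from the projection center* are exact, and distortion of chords
stays small as long as a track segment is projected about its own midpoint.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088
"""Mean Earth radius (IUGG), km — the sphere all great-circle math uses."""


def normalize_lon(lon):
    """Normalize longitudes to the interval (-180, 180]."""
    lon = np.asarray(lon, dtype=float)
    out = -np.mod(-lon + 180.0, 360.0) + 180.0
    return out if out.ndim else float(out)


def great_circle_km(lat1, lon1, lat2, lon2):
    """Haversine great-circle distance in km.

    Accepts scalars or broadcastable arrays of decimal degrees.  Symmetric,
    non-negative, and zero iff the points coincide (up to rounding).
    """
    p1, l1, p2, l2 = (np.radians(np.asarray(x, dtype=float))
                      for x in (lat1, lon1, lat2, lon2))
    dphi = p2 - p1
    dlam = l2 - l1
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return d if d.ndim else float(d)


def initial_bearing_deg(lat1, lon1, lat2, lon2):
    """Initial bearing (forward azimuth) from point 1 to point 2, degrees in [0, 360)."""
    p1, l1, p2, l2 = (np.radians(np.asarray(x, dtype=float))
                      for x in (lat1, lon1, lat2, lon2))
    dlam = l2 - l1
    y = np.sin(dlam) * np.cos(p2)
    x = np.cos(p1) * np.sin(p2) - np.sin(p1) * np.cos(p2) * np.cos(dlam)
    b = np.degrees(np.arctan2(y, x)) % 360.0
    return b if b.ndim else float(b)


def destination_point(lat, lon, bearing_deg, distance_km):
    """Point reached by travelling ``distance_km`` along ``bearing_deg`` on the great circle."""
    p1 = np.radians(np.asarray(lat, dtype=float))
    l1 = np.radians(np.asarray(lon, dtype=float))
    theta = np.radians(np.asarray(bearing_deg, dtype=float))
    delta = np.asarray(distance_km, dtype=float) / EARTH_RADIUS_KM
    p2 = np.arcsin(np.sin(p1) * np.cos(delta) + np.cos(p1) * np.sin(delta) * np.cos(theta))
    l2 = l1 + np.arctan2(np.sin(theta) * np.sin(delta) * np.cos(p1),
                         np.cos(delta) - np.sin(p1) * np.sin(p2))
    lat2 = np.degrees(p2)
    lon2 = normalize_lon(np.degrees(l2))
    if np.ndim(lat2) == 0:
        return float(lat2), float(lon2)
    return lat2, lon2


def gc_interpolate(lat1, lon1, lat2, lon2, fractions):
    """Points along the great circle from 1 to 2 at the given fractions in [0, 1].

    Spherical linear interpolation on the unit sphere; returns (lats, lons)
    arrays.  Antipodal endpoints are rejected (the great circle is ambiguous).
    """
    f = np.atleast_1d(np.asarray(fractions, dtype=float))
    v1 = _unit_vector(lat1, lon1)
    v2 = _unit_vector(lat2, lon2)
    omega = np.arccos(np.clip(np.dot(v1, v2), -1.0, 1.0))
    if omega < 1e-12:
        lats = np.full(f.shape, float(lat1))
        lons = np.full(f.shape, float(lon1))
        return lats, lons
    if np.pi - omega < 1e-9:
        raise ValueError("antipodal endpoints: great-circle path is ambiguous")
    so = np.sin(omega)
    v = (np.sin((1.0 - f) * omega)[:, None] * v1 + np.sin(f * omega)[:, None] * v2) / so
    return _vector_latlon(v)


def _unit_vector(lat, lon):
    p = np.radians(float(lat))
    l = np.radians(float(lon))
    return np.array([np.cos(p) * np.cos(l), np.cos(p) * np.sin(l), np.sin(p)])


def _vector_latlon(v):
    v = np.asarray(v, dtype=float)
    lats = np.degrees(np.arctan2(v[..., 2], np.hypot(v[..., 0], v[..., 1])))
    lons = normalize_lon(np.degrees(np.arctan2(v[..., 1], v[..., 0])))
    return lats, lons


def circular_mean_lon(lons):
    """Mean longitude via the circular mean, safe across the antimeridian."""
    l = np.radians(np.asarray(lons, dtype=float))
    return float(normalize_lon(np.degrees(np.arctan2(np.mean(np.sin(l)), np.mean(np.cos(l))))))


def aeq_forward(lat, lon, lat0, lon0):
    """Azimuthal-equidistant forward projection centered at (lat0, lon0).

    Returns planar (x, y) in km: x east, y north.  Distances from the center
    are preserved exactly; use one center per track segment.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    d = great_circle_km(lat0, lon0, lat, lon)
    az = np.radians(initial_bearing_deg(lat0, lon0, lat, lon))
    x = d * np.sin(az)
    y = d * np.cos(az)
    if np.ndim(x) == 0:
        return float(x), float(y)
    return np.asarray(x), np.asarray(y)


def aeq_inverse(x, y, lat0, lon0):
    """Inverse of :func:`aeq_forward`."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = np.hypot(x, y)
    az = np.degrees(np.arctan2(x, y))
    return destination_point(lat0, lon0, az, d)


def path_length_km(lats, lons) -> float:
    """Sum of consecutive great-circle segment lengths along a polyline, km."""
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    if lats.size < 2:
        return 0.0
    return float(np.sum(great_circle_km(lats[:-1], lons[:-1], lats[1:], lons[1:])))
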