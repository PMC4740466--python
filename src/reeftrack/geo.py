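"""Map projection and distance utilities.

Positions are recorded by receivers in geographic coordinates (WGS84
latitude/longitude) but all within-array spatial metrics are computed on a
projected plane in metres: Universal Transverse Mercator, zone 55 south,
which covers the central Great Barrier Reef (144-150 degrees E).

The forward/inverse transverse Mercator here is the Krueger series in terms
of the third flattening n, truncated at n^4.  On the WGS84 ellipsoid this
truncation is accurate to well under a millimetre anywhere inside a UTM
zone and to centimetres a few degrees outside it, which is far below the
nominal 250-350 m acoustic detection range that limits positional accuracy
in this kind of telemetry data.
"""

from __future__ import annotations

import warnings

import numpy as np

# WGS84 ellipsoid
_A = 6378137.0
_F = 1.0 / 298.257223563
_E2 = _F * (2.0 - _F)

# UTM conventions
K0 = 0.9996
FALSE_EASTING = 500_000.0
FALSE_NORTHING_SOUTH = 10_000_000.0

_N = _F / (2.0 - _F)  # third flattening
_N2, _N3, _N4 = _N**2, _N**3, _N**4

# rectifying radius
_A_RECT = _A / (1.0 + _N) * (1.0 + _N2 / 4.0 + _N4 / 64.0)

_ALPHA = (
    _N / 2.0 - 2.0 * _N2 / 3.0 + 5.0 * _N3 / 16.0 + 41.0 * _N4 / 180.0,
    13.0 * _N2 / 48.0 - 3.0 * _N3 / 5.0 + 557.0 * _N4 / 1440.0,
    61.0 * _N3 / 240.0 - 103.0 * _N4 / 140.0,
    49561.0 * _N4 / 161280.0,
)
_BETA = (
    _N / 2.0 - 2.0 * _N2 / 3.0 + 37.0 * _N3 / 96.0 - _N4 / 360.0,
    _N2 / 48.0 + _N3 / 15.0 - 437.0 * _N4 / 1440.0,
    17.0 * _N3 / 480.0 - 37.0 * _N4 / 840.0,
    4397.0 * _N4 / 161280.0,
)
# conformal latitude -> geographic latitude
_DELTA = (
    2.0 * _N - 2.0 * _N2 / 3.0 - 2.0 * _N3 + 116.0 * _N4 / 45.0,
    7.0 * _N2 / 3.0 - 8.0 * _N3 / 5.0 - 227.0 * _N4 / 45.0,
    56.0 * _N3 / 15.0 - 136.0 * _N4 / 35.0,
    4279.0 * _N4 / 630.0,
)

DEFAULT_ZONE = 55


def zone_central_meridian(zone: int) -> float:
    """Central meridian (degrees E) of a UTM longitude zone."""
    if not 1 <= zone <= 60:
        raise ValueError(f"UTM zone must be in 1..60, got {zone}")
    return -183.0 + 6.0 * zone


def project_to_utm(latitude, longitude, zone: int = DEFAULT_ZONE, south: bool = True):
    """Project WGS84 geographic coordinates to UTM easting/northing (metres).

    Accepts scalars or array-likes; returns a pair of ndarrays (or floats for
    scalar input).  Points more than ~7 degrees of longitude from the zone's
    central meridian trigger a warning but are still projected (the series
    remains usable for the long along-coast spans this package measures).
    """
    lat = np.asarray(latitude, dtype=float)
    lon = np.asarray(longitude, dtype=float)
    if not (np.all(np.isfinite(lat)) and np.all(np.isfinite(lon))):
        raise ValueError("latitude/longitude must be finite")
    if np.any(np.abs(lat) > 84.0):
        raise ValueError("latitude outside transverse Mercator validity (|lat| > 84)")
    lon0 = zone_central_meridian(zone)
    dlon = (lon - lon0 + 180.0) % 360.0 - 180.0
    if np.any(np.abs(dlon) > 7.0):
        warnings.warn(
            f"point(s) more than 7 deg of longitude from zone {zone} central "
            "meridian; projection is extrapolated",
            stacklevel=2,
        )

    phi = np.radians(lat)
    lam = np.radians(dlon)
    e_prime = 2.0 * np.sqrt(_N) / (1.0 + _N)
    s = np.sin(phi)
    t = np.sinh(np.arctanh(s) - e_prime * np.arctanh(e_prime * s))
    xi_p = np.arctan2(t, np.cos(lam))
    eta_p = np.arctanh(np.sin(lam) / np.sqrt(1.0 + t * t))

    xi = xi_p.copy()
    eta = eta_p.copy()
    for j, a in enumerate(_ALPHA, start=1):
        xi = xi + a * np.sin(2 * j * xi_p) * np.cosh(2 * j * eta_p)
        eta = eta + a * np.cos(2 * j * xi_p) * np.sinh(2 * j * eta_p)

    easting = FALSE_EASTING + K0 * _A_RECT * eta
    northing = K0 * _A_RECT * xi
    if south:
        northing = northing + FALSE_NORTHING_SOUTH
    if easting.ndim == 0:
        return float(easting), float(northing)
    return easting, northing


def utm_to_latlon(easting, northing, zone: int = DEFAULT_ZONE, south: bool = True):
    """Inverse of :func:`project_to_utm`; returns (latitude, longitude)."""
    x = np.asarray(easting, dtype=float)
    y = np.asarray(northing, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("easting/northing must be finite")
    if south:
        y = y - FALSE_NORTHING_SOUTH
    xi = y / (K0 * _A_RECT)
    eta = (x - FALSE_EASTING) / (K0 * _A_RECT)

    xi_p = xi.copy()
    eta_p = eta.copy()
    for j, b in enumerate(_BETA, start=1):
        xi_p = xi_p - b * np.sin(2 * j * xi) * np.cosh(2 * j * eta)
        eta_p = eta_p - b * np.cos(2 * j * xi) * np.sinh(2 * j * eta)

    chi = np.arcsin(np.clip(np.sin(xi_p) / np.cosh(eta_p), -1.0, 1.0))
    phi = chi.copy()
    for j, d in enumerate(_DELTA, start=1):
        phi = phi + d * np.sin(2 * j * chi)
    lam = np.arctan2(np.sinh(eta_p), np.cos(xi_p))

    lat = np.degrees(phi)
    lon = zone_central_meridian(zone) + np.degrees(lam)
    if lat.ndim == 0:
        return float(lat), float(lon)
    return lat, lon


def planar_distance_m(e1, n1, e2, n2):
    """Euclidean distance (m) between projected points."""
    e1, n1, e2, n2 = (np.asarray(v, dtype=float) for v in (e1, n1, e2, n2))
    return np.hypot(e2 - e1, n2 - n1)


# mean Earth radius, IUGG
_R_MEAN = 6371008.8


def geodesic_distance_m(lat1, lon1, lat2, lon2):
    """Great-circle (haversine) distance in metres on the mean Earth sphere.

    Offered as an alternative to planar UTM distances for spans long enough
    that projection distortion matters; sub-0.5% error at these latitudes.
    """
    p1, l1, p2, l2 = (np.radians(np.asarray(v, dtype=float)) for v in (lat1, lon1, lat2, lon2))
    dphi = p2 - p1
    dlam = l2 - l1
    h = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * _R_MEAN * np.arcsin(np.sqrt(h))
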