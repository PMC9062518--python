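"""Cylindrical equal-area (CEA) projection on a spherical earth.

All spatial computations in this package (neighbor search, window counts,
prediction grids) happen in projected meters of a Lambert cylindrical
equal-area projection. The default standard parallel is 30°S, which keeps
cell-area distortion small over mid-latitude continents while preserving the
equal-area property exactly.
"""

from __future__ import annotations

import numpy as np

#: Mean authalic sphere radius in meters (GRS80/WGS84 authalic value).
EARTH_RADIUS_M = 6_371_007.2

DEFAULT_STANDARD_PARALLEL = -30.0


def project_cea(lon, lat, standard_parallel: float = DEFAULT_STANDARD_PARALLEL,
                radius: float = EARTH_RADIUS_M):
    """Forward Lambert cylindrical equal-area projection.

    Parameters
    ----------
    lon, lat : array_like
        Geographic coordinates in degrees. ``|lat|`` must not exceed 90.
    standard_parallel : float
        Latitude of true scale in degrees (default −30°).
    radius : float
        Sphere radius in meters.

    Returns
    -------
    x, y : ndarray or float
        Projected coordinates in meters:
        ``x = R·λ·cos(φs)``, ``y = R·sin(φ)/cos(φs)``.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude out of range [-90, 90]")
    cos_sp = np.cos(np.deg2rad(standard_parallel))
    x = radius * np.deg2rad(lon) * cos_sp
    y = radius * np.sin(np.deg2rad(lat)) / cos_sp
    if x.ndim == 0:
        return float(x), float(y)
    return x, y


def inverse_cea(x, y, standard_parallel: float = DEFAULT_STANDARD_PARALLEL,
                radius: float = EARTH_RADIUS_M):
    """Inverse of :func:`project_cea`; returns (lon, lat) in degrees."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cos_sp = np.cos(np.deg2rad(standard_parallel))
    lon = np.rad2deg(x / (radius * cos_sp))
    sin_lat = y * cos_sp / radius
    if np.any(np.abs(sin_lat) > 1.0 + 1e-12):
        raise ValueError("y coordinate outside the projectable range")
    lat = np.rad2deg(np.arcsin(np.clip(sin_lat, -1.0, 1.0)))
    if lon.ndim == 0:
        return float(lon), float(lat)
    return lon, lat
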