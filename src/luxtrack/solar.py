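"""Solar geometry: elevation angle, declination, equation of time, terminator.

Positions are geodetic longitude/latitude in degrees; times are UTC.  The
solar position algorithm is a Meeus-style low-precision series (geometric
mean longitude, equation of centre, apparent longitude with the leading
nutation term), good to well under 0.1 degree in elevation over 1950-2050.
No atmospheric refraction is applied: the irradiance template downstream is
a function of the geometric solar angle, and refraction variability is part
of the observation noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GeoPosition",
    "solar_elevation",
    "solar_elevation_grid",
    "declination_eot",
    "equator_crossing_longitude",
]

_J2000 = np.datetime64("2000-01-01T12:00:00", "s")
_DEG = np.pi / 180.0


def wrap_lon(lon):
    """Normalize longitude(s) to the half-open interval [-180, 180)."""
    return (np.asarray(lon, dtype=float) + 180.0) % 360.0 - 180.0


@dataclass(frozen=True)
class GeoPosition:
    """A point on the sphere: longitude degrees east, latitude degrees north."""

    lon: float
    lat: float

    def __post_init__(self):
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        object.__setattr__(self, "lon", float(wrap_lon(self.lon)))
        object.__setattr__(self, "lat", float(self.lat))


def _as_seconds(t):
    """Convert times (datetime64, datetime, pandas, ISO strings) to float
    seconds since J2000 (UTC)."""
    arr = np.asarray(t)
    if arr.dtype.kind != "M":
        arr = arr.astype("datetime64[s]")
    return (arr.astype("datetime64[s]") - _J2000) / np.timedelta64(1, "s")


def _sun_params(sec):
    """Declination (deg), equation of time (minutes) and UTC minutes past
    midnight for times given in seconds since J2000."""
    T = sec / (36525.0 * 86400.0)  # Julian centuries since J2000
    L0 = (280.46646 + 36000.76983 * T + 0.0003032 * T * T) % 360.0
    M = 357.52911 + 35999.05029 * T - 0.0001537 * T * T
    e = 0.016708634 - 0.000042037 * T - 0.0000001267 * T * T
    Mr = M * _DEG
    C = (
        (1.914602 - 0.004817 * T - 0.000014 * T * T) * np.sin(Mr)
        + (0.019993 - 0.000101 * T) * np.sin(2 * Mr)
        + 0.000289 * np.sin(3 * Mr)
    )
    true_lon = L0 + C
    omega = (125.04 - 1934.136 * T) * _DEG
    app_lon = (true_lon - 0.00569 - 0.00478 * np.sin(omega)) * _DEG
    eps0 = 23.439291111 - 0.013004167 * T - 1.638889e-7 * T * T
    eps = (eps0 + 0.00256 * np.cos(omega)) * _DEG
    decl = np.arcsin(np.sin(eps) * np.sin(app_lon)) / _DEG

    y = np.tan(eps / 2.0) ** 2
    L0r = L0 * _DEG
    eot = 4.0 / _DEG * (
        y * np.sin(2 * L0r)
        - 2.0 * e * np.sin(Mr)
        + 4.0 * e * y * np.sin(Mr) * np.cos(2 * L0r)
        - 0.5 * y * y * np.sin(4 * L0r)
        - 1.25 * e * e * np.sin(2 * Mr)
    )
    utc_min = (sec / 60.0 + 720.0) % 1440.0  # J2000 epoch is 12:00 UTC
    return decl, eot, utc_min


def declination_eot(t):
    """Solar declination (degrees) and equation of time (minutes) at UTC ``t``.

    The equation of time is apparent minus mean solar time; positive when the
    sundial runs ahead of the clock.
    """
    decl, eot, _ = _sun_params(_as_seconds(t))
    return decl, eot


def _elevation(lon, lat, decl, eot, utc_min):
    tst = (utc_min + eot + 4.0 * lon) % 1440.0
    H = (tst / 4.0 - 180.0) * _DEG
    latr = np.asarray(lat, dtype=float) * _DEG
    dr = decl * _DEG
    sin_el = np.sin(latr) * np.sin(dr) + np.cos(latr) * np.cos(dr) * np.cos(H)
    return np.arcsin(np.clip(sin_el, -1.0, 1.0)) / _DEG


def solar_elevation(pos, t):
    """Geometric (unrefracted) solar elevation angle in degrees.

    ``pos`` may be a :class:`GeoPosition` or an ``(lon, lat)`` pair of scalars
    or broadcastable arrays; ``t`` is a UTC instant or array of instants.
    """
    if isinstance(pos, GeoPosition):
        lon, lat = pos.lon, pos.lat
    else:
        lon, lat = pos
    decl, eot, utc_min = _sun_params(_as_seconds(t))
    out = _elevation(np.asarray(lon, dtype=float), lat, decl, eot, utc_min)
    return float(out) if np.ndim(out) == 0 else out


def solar_elevation_grid(lons, lats, t):
    """Elevation for every (node, time) pair: shape ``(n_nodes, n_times)``.

    Computes the time-only solar terms once and broadcasts over nodes, which
    is the hot path when scoring a twilight at every grid node.
    """
    decl, eot, utc_min = _sun_params(_as_seconds(t))
    lons = np.asarray(lons, dtype=float)[:, None]
    lats = np.asarray(lats, dtype=float)[:, None]
    return _elevation(lons, lats, decl[None, :], eot[None, :], utc_min[None, :])


def equator_crossing_longitude(t, kind):
    """Longitude at which the day/night terminator crosses the equator.

    At any instant the terminator (solar elevation = 0) is a great circle
    meeting the equator at two points: one where the sun is rising
    (``kind="rise"``, local hour angle -90 deg) and one where it is setting
    (``kind="set"``, +90 deg).  Used as a one-number-per-twilight longitude
    diagnostic for outlier screening; for a stationary tag the series is
    nearly constant, so jumps flag bad twilights.
    """
    if kind not in ("rise", "set"):
        raise ValueError(f"kind must be 'rise' or 'set', got {kind!r}")
    _, eot, utc_min = _sun_params(_as_seconds(t))
    tst_target = 360.0 if kind == "rise" else 1080.0  # minutes: 06:00 / 18:00
    lon = (tst_target - utc_min - eot) / 4.0
    out = wrap_lon(lon)
    return float(out) if np.ndim(out) == 0 else out
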