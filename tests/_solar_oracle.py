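"""Independent solar-position oracle for the tests.

Implements the Astronomical Almanac low-precision algorithm of Michalsky
(1988), accurate to ~0.01 degrees over 1950-2050.  Deliberately coded from
that paper's formulation (mean longitude / mean anomaly / ecliptic
longitude / sidereal time), sharing no code or coefficients with
``luxtrack.solar``, so agreement between the two is a real cross-check.
"""

import numpy as np

_J2000 = np.datetime64("2000-01-01T12:00:00", "s")


def _days(t):
    return (np.datetime64(t, "s") - _J2000) / np.timedelta64(1, "s") / 86400.0


def sun_position(t):
    """(right ascension deg, declination deg, eq. of time minutes) at UTC t."""
    n = _days(t)
    L = (280.460 + 0.9856474 * n) % 360.0
    g = np.radians((357.528 + 0.9856003 * n) % 360.0)
    lam = np.radians(L + 1.915 * np.sin(g) + 0.020 * np.sin(2 * g))
    ep = np.radians(23.439 - 0.0000004 * n)
    ra = np.degrees(np.arctan2(np.cos(ep) * np.sin(lam), np.cos(lam))) % 360.0
    dec = np.degrees(np.arcsin(np.sin(ep) * np.sin(lam)))
    # equation of time from the gap between mean sun and apparent RA
    eot = ((L - ra + 180.0) % 360.0 - 180.0) * 4.0
    return ra, dec, eot


def elevation(lon, lat, t):
    """Geometric solar elevation (degrees) via Michalsky's algorithm."""
    n = _days(t)
    ra, dec, _ = sun_position(t)
    ut_hours = ((_days(t) % 1.0) * 24.0 + 12.0) % 24.0
    gmst = (6.697375 + 0.0657098242 * n + ut_hours) % 24.0
    lmst = (gmst + lon / 15.0) % 24.0
    ha = np.radians(((lmst * 15.0 - ra) + 180.0) % 360.0 - 180.0)
    latr, decr = np.radians(lat), np.radians(dec)
    sin_el = np.sin(latr) * np.sin(decr) + np.cos(latr) * np.cos(decr) * np.cos(ha)
    return float(np.degrees(np.arcsin(np.clip(sin_el, -1, 1))))
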