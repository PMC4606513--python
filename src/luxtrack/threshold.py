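"""Classic threshold geolocation: longitude from the twilight midpoint,
latitude from day length, after calibrating the sun elevation angle that the
light threshold corresponds to at a known site.

Serves as the baseline the template-fit filter is compared against.  Its
well-known failure mode is the equinox: day length is then almost invariant
with latitude, so latitude is unidentifiable (returned as missing when the
day-length equation has no solution) and noisy around the equinoxes.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

from .lightio import detect_twilights
from .solar import GeoPosition, declination_eot, solar_elevation

__all__ = [
    "ThresholdFix",
    "calibrate_sun_angle",
    "threshold_fix",
    "threshold_track",
    "monthly_fix_stats",
]

_DEG = np.pi / 180.0


@dataclass
class ThresholdFix:
    date: date
    lon: float
    lat: float | None  # None when day length admits no latitude (equinox)
    sun_angle: float


def choose_threshold_level(series, calib_period, candidates=(1, 2, 4, 8, 16, 32), min_pairs=10):
    """Smallest light level whose crossings allow sun-angle calibration.

    The classic method prefers the lowest level above dark (closest to the
    sensitive part of the twilight curve), but bright high-latitude summer
    nights may never cross a low level during the calibration month; this
    walks up a level ladder until at least ``min_pairs`` rise/set pairs fall
    inside ``calib_period``.
    """
    t0 = np.datetime64(calib_period[0], "s")
    t1 = np.datetime64(calib_period[1], "s")
    for level in candidates:
        events = detect_twilights(series, level=level)
        n = sum(1 for t, _ in events if t0 <= np.datetime64(t, "s") <= t1)
        if n // 2 >= min_pairs:
            return float(level)
    raise ValueError("no candidate level yields enough calibration twilights")


def calibrate_sun_angle(events, known, period=None):
    """Median solar elevation at the known site over threshold crossings.

    ``events`` are (anchor_time, kind) pairs; ``period`` restricts to
    (start, end).  Requires at least 10 rise/set pairs.
    """
    times = [np.datetime64(t, "s") for t, _ in events]
    if period is not None:
        t0, t1 = np.datetime64(period[0], "s"), np.datetime64(period[1], "s")
        times = [t for t in times if t0 <= t <= t1]
    if len(times) // 2 < 10:
        raise ValueError(
            f"need >= 10 twilight pairs for sun-angle calibration, have {len(times) // 2}"
        )
    angles = solar_elevation(known, np.array(times, dtype="datetime64[s]"))
    return float(np.median(angles))


def _lat_from_daylength(H0_deg, decl_deg, sun_angle_deg, prev_lat=None):
    """Latitudes solving sin(e) = sin(phi)sin(d) + cos(phi)cos(d)cos(H0).

    The equation can have zero, one or two roots in [-89, 89]; with two,
    the one nearest ``prev_lat`` (or of smallest magnitude) is returned.
    """
    H0 = H0_deg * _DEG
    d = decl_deg * _DEG
    target = np.sin(sun_angle_deg * _DEG)

    def g(phi_deg):
        phi = phi_deg * _DEG
        return np.sin(phi) * np.sin(d) + np.cos(phi) * np.cos(d) * np.cos(H0) - target

    phis = np.linspace(-89.0, 89.0, 357)  # 0.5 degree scan
    vals = g(phis)
    roots = []
    from scipy.optimize import brentq

    for k in range(phis.size - 1):
        if vals[k] == 0.0:
            roots.append(phis[k])
        elif vals[k] * vals[k + 1] < 0:
            roots.append(brentq(g, phis[k], phis[k + 1], xtol=1e-8))
    if not roots:
        return None
    if len(roots) == 1:
        return float(roots[0])
    roots = np.asarray(roots)
    if prev_lat is not None:
        return float(roots[np.argmin(np.abs(roots - prev_lat))])
    return float(roots[np.argmin(np.abs(roots))])


def threshold_fix(rise, set_, sun_angle, prev_lat=None):
    """One daily position fix from a rise/set pair of threshold crossings."""
    rise = np.datetime64(rise, "s")
    set_ = np.datetime64(set_, "s")
    day_s = (set_ - rise) / np.timedelta64(1, "s")
    if day_s <= 0 or day_s >= 86400:
        raise ValueError("rise must precede set within 24 h")
    mid = rise + np.timedelta64(int(round(day_s / 2)), "s")
    decl, eot = declination_eot(mid)
    utc_min = (
        (mid - mid.astype("datetime64[D]").astype("datetime64[s]"))
        / np.timedelta64(1, "s")
        / 60.0
    )
    lon = (720.0 - utc_min - eot) / 4.0  # solar noon at the midpoint
    lon = (lon + 180.0) % 360.0 - 180.0
    H0_deg = day_s / 3600.0 / 2.0 * 15.0  # half day length as hour angle
    lat = _lat_from_daylength(H0_deg, float(decl), sun_angle, prev_lat)
    return ThresholdFix(
        date=pd.Timestamp(mid).date(), lon=float(lon), lat=lat, sun_angle=sun_angle
    )


def threshold_track(series, level, known, calib_period, min_gap_h=4.0):
    """Threshold fixes for a whole series, calibrated at ``known`` in
    ``calib_period``; returns a DataFrame (date, lon, lat, lat_missing)."""
    from datetime import timedelta

    from collections import deque

    events = detect_twilights(series, level=level, min_gap=timedelta(hours=min_gap_h))
    sun_angle = calibrate_sun_angle(events, known, calib_period)
    fixes = []
    # root disambiguation follows a robust reference: the median of the last
    # few accepted latitudes, seeded at the known calibration site, so a
    # single noisy equinox fix cannot flip the chain onto the mirror branch
    recent = deque([known.lat if isinstance(known, GeoPosition) else known[1]], maxlen=7)
    for (t0, k0), (t1, k1) in zip(events[:-1], events[1:]):
        if k0 != "rise" or k1 != "set":
            continue
        if (np.datetime64(t1, "s") - np.datetime64(t0, "s")) / np.timedelta64(1, "h") >= 24:
            continue
        ref = float(np.median(recent))
        fix = threshold_fix(t0, t1, sun_angle, ref)
        # equinox-season fixes scatter over tens of degrees; only plausible
        # day-to-day moves may update the reference, or one bad week near
        # the equinox would drag the chain onto the mirror branch for good
        if fix.lat is not None and abs(fix.lat - ref) <= 15.0:
            recent.append(fix.lat)
        fixes.append(fix)
    return pd.DataFrame(
        {
            "date": [f.date for f in fixes],
            "lon": [f.lon for f in fixes],
            "lat": [np.nan if f.lat is None else f.lat for f in fixes],
            "lat_missing": [f.lat is None for f in fixes],
            "sun_angle": sun_angle,
        }
    )


def monthly_fix_stats(fixes, truth_lon, truth_lat):
    """Monthly bias/SD of threshold fixes against a known position."""
    df = fixes.copy()
    df["lat_error"] = df["lat"] - truth_lat
    df["lon_error"] = (df["lon"] - truth_lon + 180.0) % 360.0 - 180.0
    df["month"] = pd.to_datetime(df["date"]).dt.month
    g = df.groupby("month")
    return pd.DataFrame(
        {
            "bias_lat": g["lat_error"].mean(),
            "sd_lat": g["lat_error"].std(ddof=1),
            "bias_lon": g["lon_error"].mean(),
            "sd_lon": g["lon_error"].std(ddof=1),
            "n": g.size(),
            "n_lat": g["lat_error"].count(),
        }
    )
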