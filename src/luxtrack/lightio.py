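"""Reading, writing and segmenting archival light records.

Archival tags store the maximum light level seen over a fixed interval
(2-10 min), clipped to integer device units in [0, 64].  Three dialects are
supported: BAS ``.lig`` (flag, date-time, seconds, light), a generic CSV
(ISO datetime, light), and annotation-service exports (datetime, light,
twilight, excluded).  All timestamps are treated as UTC; no clock-drift
correction is attempted.

Twilight handling: crossings of a light threshold are located by linear
interpolation in raw light units, spurious short excursions are cancelled,
and each surviving event is given a measurement window clipped at the
estimated solar noon/midnight boundaries.  Within the window, readings
strictly between the device bounds are regular samples; clipped readings
near the anchor (dark zeros and saturated 64s) are kept as censored
observations so the fit can use the timing of entry into darkness and
saturation without the selection bias that silently dropping them causes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import timedelta

import numpy as np
import pandas as pd

__all__ = [
    "LightSeries",
    "TwilightData",
    "read_light_series",
    "write_light_series",
    "detect_twilights",
    "assemble_twilight",
    "extract_twilights",
    "read_annotations",
    "write_annotations",
]

LIGHT_MIN, LIGHT_MAX = 0, 64


@dataclass
class LightSeries:
    """Timestamped clipped light measurements from one tag."""

    times: np.ndarray  # datetime64[s], strictly increasing, constant interval
    light: np.ndarray  # integer device units in [0, 64]

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype="datetime64[s]")
        self.light = np.asarray(self.light)
        if self.times.size != self.light.size:
            raise ValueError("times and light must have equal length")
        if self.times.size >= 2:
            dt = np.diff(self.times).astype("timedelta64[s]").astype(np.int64)
            if np.any(dt <= 0):
                row = int(np.argmax(dt <= 0)) + 1
                raise ValueError(f"timestamps not strictly increasing at row {row}")
            if dt.max() - dt.min() > 1:
                raise ValueError("inter-record interval not constant (tolerance 1 s)")
        if np.any(self.light < LIGHT_MIN) or np.any(self.light > LIGHT_MAX):
            raise ValueError(f"light outside [{LIGHT_MIN}, {LIGHT_MAX}]")
        self.light = self.light.astype(np.int64)

    def __len__(self):
        return self.times.size

    @property
    def interval_s(self):
        if len(self) < 2:
            raise ValueError("need at least two records for an interval")
        return float(
            np.diff(self.times).astype("timedelta64[s]").astype(np.int64).mean()
        )

    @property
    def records(self):
        return list(zip(self.times, self.light))


@dataclass
class TwilightData:
    """One twilight event: anchor crossing plus its measurement window."""

    index: int
    kind: str  # "rise" | "set"
    anchor_time: np.datetime64
    times: np.ndarray = field(default_factory=lambda: np.array([], dtype="datetime64[s]"))
    log_light: np.ndarray = field(default_factory=lambda: np.array([], dtype=float))
    excluded: bool = False
    reason: str = ""

    def __post_init__(self):
        if self.kind not in ("rise", "set"):
            raise ValueError(f"kind must be 'rise' or 'set', got {self.kind!r}")
        self.times = np.asarray(self.times, dtype="datetime64[s]")
        self.log_light = np.asarray(self.log_light, dtype=float)
        if self.times.size:
            if np.any(np.diff(self.times).astype(np.int64) < 0):
                raise ValueError("samples must be time-ordered")
            if not np.all(np.isfinite(self.log_light)):
                raise ValueError("log_light must be finite (no zero-light samples)")
        if self.excluded and not self.reason:
            raise ValueError("excluded twilights need a reason code")

    @property
    def n_samples(self):
        return self.times.size


def _parse_times(raw, dialect, fmt=None):
    try:
        if fmt:
            return pd.to_datetime(raw, format=fmt).values.astype("datetime64[s]")
        return pd.to_datetime(raw, format="ISO8601").values.astype("datetime64[s]")
    except (ValueError, TypeError) as exc:
        # locate the first offending row for the error message
        for i, v in enumerate(raw):
            try:
                pd.to_datetime(v, format=fmt) if fmt else pd.to_datetime(
                    v, format="ISO8601"
                )
            except (ValueError, TypeError):
                raise ValueError(
                    f"unparseable timestamp {v!r} at data row {i + 1} ({dialect})"
                ) from exc
        raise


def read_light_series(path, dialect="csv"):
    """Read a light series; ``dialect`` is ``bas_lig``, ``csv`` or ``tags_export``."""
    if dialect == "bas_lig":
        df = pd.read_csv(
            path, header=None, names=["flag", "datetime", "seconds", "light"]
        )
        df = df[df["flag"].astype(str).str.strip().str.lower() == "ok"]
        times = _parse_times(df["datetime"].str.strip(), dialect, fmt="%d/%m/%y %H:%M:%S")
    elif dialect == "csv":
        df = pd.read_csv(path)
        _require_columns(df, ["datetime", "light"], dialect)
        times = _parse_times(df["datetime"], dialect)
    elif dialect == "tags_export":
        df = pd.read_csv(path)
        _require_columns(df, ["datetime", "light"], dialect)
        times = _parse_times(df["datetime"], dialect)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return LightSeries(times, df["light"].to_numpy())


def _require_columns(df, cols, dialect):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{dialect} file missing columns {missing}")


def write_light_series(path, series, dialect="csv"):
    if dialect == "csv":
        pd.DataFrame(
            {
                "datetime": np.datetime_as_string(series.times, unit="s"),
                "light": series.light,
            }
        ).to_csv(path, index=False)
    elif dialect == "bas_lig":
        secs = series.times.astype("datetime64[s]").astype(np.int64)
        stamps = pd.to_datetime(series.times).strftime("%d/%m/%y %H:%M:%S")
        pd.DataFrame(
            {"flag": "ok", "datetime": stamps, "seconds": secs, "light": series.light}
        ).to_csv(path, index=False, header=False)
    else:
        raise ValueError(f"unsupported write dialect {dialect!r}")


def detect_twilights(series, level=32.0, min_gap=timedelta(hours=4)):
    """Threshold crossings of the light series: (anchor_time, kind) per event.

    A dark-to-light crossing of ``level`` is a rise, light-to-dark a set;
    crossing times are linearly interpolated in raw light units between the
    bracketing records.  Crossing pairs bounding an excursion shorter than
    ``min_gap`` (a brief dip or blip) cancel each other, shortest first.
    An entirely dark or entirely light series yields an empty list.
    """
    if not (LIGHT_MIN < level < LIGHT_MAX):
        raise ValueError(f"level must be strictly inside ({LIGHT_MIN}, {LIGHT_MAX})")
    light = series.light.astype(float)
    below = light < level
    idx = np.flatnonzero(below[:-1] != below[1:])
    if idx.size == 0:
        return []
    t0 = series.times[idx].astype("datetime64[s]").astype(np.int64).astype(float)
    t1 = series.times[idx + 1].astype("datetime64[s]").astype(np.int64).astype(float)
    frac = (level - light[idx]) / (light[idx + 1] - light[idx])
    anchors = t0 + frac * (t1 - t0)
    kinds = np.where(below[idx], "rise", "set")

    times = list(anchors)
    kinds = list(kinds)
    gap_s = min_gap.total_seconds() if isinstance(min_gap, timedelta) else float(min_gap)
    # cancel the shortest sub-threshold-gap crossing pair until all gaps pass
    while len(times) >= 2:
        gaps = np.diff(times)
        k = int(np.argmin(gaps))
        if gaps[k] >= gap_s:
            break
        del times[k : k + 2]
        del kinds[k : k + 2]
    return [
        (np.datetime64(int(round(t)), "s"), str(k)) for t, k in zip(times, kinds)
    ]


# log value stored for dark (0) records; the fit reads any sample at or
# below this value as left-censored (underlying reading below half a unit)
DARK_LOG = float(np.log(0.5))


def assemble_twilight(
    series,
    anchor,
    window=timedelta(minutes=240),
    saturation_pad=1,
    index=0,
    bounds=None,
    censor_window=timedelta(minutes=90),
):
    """Build the measurement window for one twilight event.

    Samples are all records within ``window`` of the anchor with
    0 < light < 64 (stored as log device units; the fit treats each integer
    as its quantization interval), plus clipped records near the anchor kept
    as censored observations: saturated (64) records within
    ``censor_window`` -- and at least ``saturation_pad`` bounding ones --
    recoded at the clip value, and dark (0) records within ``censor_window``
    recoded at ``DARK_LOG`` (the log upper bound of a zero reading).
    Censored boundary records anchor the timing of the transition; dark
    records far from the twilight carry no shape information and are
    dropped.  ``bounds`` optionally clips the window to (t_lo, t_hi) --
    used to keep a twilight's samples away from the neighbouring event,
    since the attenuation intercept is only constant within one twilight
    period.  An empty window yields an excluded event.
    """
    anchor_time, kind = anchor
    if isinstance(window, timedelta):
        window = window.total_seconds()
    if isinstance(censor_window, timedelta):
        censor_window = censor_window.total_seconds()
    if window <= 0:
        raise ValueError("window must be positive")
    anchor_time = np.datetime64(anchor_time, "s")
    dt = (series.times - anchor_time) / np.timedelta64(1, "s")
    in_win = np.abs(dt) <= window
    if bounds is not None:
        t_lo, t_hi = (np.datetime64(b, "s") for b in bounds)
        in_win &= (series.times >= t_lo) & (series.times <= t_hi)
    near = in_win & (np.abs(dt) <= censor_window)
    light = series.light
    usable = in_win & (light > LIGHT_MIN) & (light < LIGHT_MAX)
    sel = np.flatnonzero(usable)
    sat_near = np.flatnonzero(near & (light == LIGHT_MAX))
    dark_near = np.flatnonzero(near & (light == LIGHT_MIN))
    pad_idx = []
    if sel.size and saturation_pad > 0:
        sat_all = np.flatnonzero(in_win & (light == LIGHT_MAX))
        before = sat_all[sat_all < sel[0]]
        after = sat_all[sat_all > sel[-1]]
        pad_idx = list(before[-saturation_pad:]) + list(after[:saturation_pad])
    keep = np.unique(
        np.concatenate(
            [sel, sat_near, dark_near, np.asarray(pad_idx, dtype=int)]
        ).astype(int)
    )
    if keep.size == 0 or sel.size == 0:
        return TwilightData(index, kind, anchor_time, excluded=True, reason="empty")
    vals = light[keep].astype(float)
    log_light = np.where(vals == LIGHT_MIN, DARK_LOG, np.log(np.maximum(vals, 0.5)))
    return TwilightData(index, kind, anchor_time, series.times[keep], log_light)


def extract_twilights(
    series,
    level=32.0,
    min_gap=timedelta(hours=4),
    window=timedelta(minutes=240),
    saturation_pad=1,
    censor_window=timedelta(minutes=90),
):
    """detect + assemble: the full list of TwilightData for a series.

    Each event's window is additionally clipped at the estimated twilight
    period boundaries (solar noon and midnight, where the per-twilight
    attenuation intercept redraws), so samples never leak across periods.
    The boundaries are read off the light series itself: solar midnight is
    the midpoint of the running-minimum plateau between a set and the next
    rise, solar noon the midpoint of the maximum plateau of the day -- this
    stays correct even when whole twilights go undetected (bright
    high-latitude nights) or when shading shifts the crossings asymmetrically.
    """
    events = detect_twilights(series, level=level, min_gap=min_gap)
    anchors = np.array([np.datetime64(t, "s") for t, _ in events])
    idx = np.searchsorted(series.times, anchors)

    # smooth (~90 min running mean) before locating diel extrema, so sample
    # noise does not jitter the estimated noon/midnight by several records
    if len(series) >= 2:
        width = max(1, int(round(5400.0 / series.interval_s)) | 1)
        kernel = np.ones(width) / width
        smooth = np.convolve(series.light.astype(float), kernel, mode="same")
    else:
        smooth = series.light.astype(float)

    def _extremum(i0, i1, minimum):
        seg = smooth[i0:i1]
        if seg.size == 0:
            return series.times[min(i0, len(series) - 1)]
        target = seg.min() if minimum else seg.max()
        at = np.flatnonzero(np.abs(seg - target) < 1e-9)
        return series.times[i0 + int(round((at[0] + at[-1]) / 2))]

    out = []
    for i, (t, kind) in enumerate(events):
        # boundary behind: midnight precedes a rise, noon precedes a set
        if i > 0:
            lo = _extremum(idx[i - 1], idx[i], minimum=(kind == "rise"))
        else:
            lo = series.times[0]
        if i + 1 < len(events):
            hi = _extremum(idx[i], idx[i + 1], minimum=(kind == "set"))
        else:
            hi = series.times[-1]
        ev = (t, kind)
        out.append(
            assemble_twilight(
                series,
                ev,
                window=window,
                saturation_pad=saturation_pad,
                index=i,
                bounds=(lo, hi),
                censor_window=censor_window,
            )
        )
    return out


_KIND_TOKENS = {
    "rise": "rise",
    "set": "set",
    "sunrise": "rise",
    "sunset": "set",
    "1": "rise",
    "2": "set",
}


def write_annotations(path, twilights, level=None):
    """Write a twilight annotation table (datetime, light, twilight, excluded)."""
    rows = [
        {
            "datetime": np.datetime_as_string(np.datetime64(tw.anchor_time, "s"), unit="s"),
            "light": "" if level is None else level,
            "twilight": tw.kind,
            "excluded": tw.excluded,
        }
        for tw in twilights
    ]
    pd.DataFrame(rows, columns=["datetime", "light", "twilight", "excluded"]).to_csv(
        path, index=False
    )


def read_annotations(path):
    """Read an annotation table back into anchor-only TwilightData records."""
    df = pd.read_csv(path)
    _require_columns(df, ["datetime", "twilight", "excluded"], "annotations")
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        token = str(row.twilight).strip().lower()
        if token not in _KIND_TOKENS:
            raise ValueError(f"unknown twilight-kind token {row.twilight!r} at row {i + 1}")
        excluded = bool(row.excluded) if not isinstance(row.excluded, str) else (
            row.excluded.strip().lower() in ("true", "1", "yes")
        )
        out.append(
            TwilightData(
                i,
                _KIND_TOKENS[token],
                np.datetime64(pd.to_datetime(row.datetime).to_datetime64(), "s"),
                excluded=excluded,
                reason="annotated" if excluded else "",
            )
        )
    return out
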