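"""Per-twilight spatial likelihood surfaces and the pre-run outlier screen.

For twilight i and candidate node k, an interval-likelihood template fit
gives a slope estimate Z_hat with standard error sigma_Z; the node's
likelihood is the overlap integral of the calibrated slope prior with that
estimate,

    L_k = integral over Z > 0 of
          logNormal(Z; meanlog_Z, sdlog_Z) * Normal(Z; Z_hat_k, sigma_Z_k) dZ,

evaluated by fixed 201-point trapezoid quadrature on a window centred on the
precision-weighted product of the two densities.  Nodes where the fit fails
get zero raw likelihood; the whole surface is floored at 1e-6 of its maximum
(so no node is ever exactly impossible, which would let a single bad
twilight extinguish the particle filter) and normalized to sum to one.

The pre-run screen maps each twilight to the longitude where the terminator
crosses the equator and flags points far from a running median in robust
(MAD) units -- a cheap, deterministic stand-in for generic time-series
outlier detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import ageing_slope
from .solar import equator_crossing_longitude, solar_elevation_grid
from .template import log_surface_light

__all__ = [
    "SurfaceError",
    "LikelihoodSurface",
    "twilight_likelihood",
    "build_surfaces",
    "prefilter_outliers",
    "surfaces_to_table",
]

FLOOR_EPS = 1e-6
N_QUAD = 201


class SurfaceError(ValueError):
    """No grid node admits a template fit for this twilight."""


@dataclass
class LikelihoodSurface:
    twilight_index: int
    weights: np.ndarray  # nonnegative, sums to 1
    flagged_outlier: bool = False
    anchor_time: np.datetime64 | None = None
    kind: str | None = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("surface weights must sum to 1")


def _batch_fit(theta, y, sigma_err=None):
    """Per-node interval-likelihood fit of quantized log light on f''(theta).

    theta: (n_nodes, n_samples); y: (n_samples,).  Returns (slope, se, valid);
    delegates to :func:`luxtrack.calibration.interval_mle_fit`, pinning the
    noise SD at the calibrated ``sigma_err`` when given.
    """
    from .calibration import CENSOR_HI, CENSOR_LO, interval_mle_fit

    b = log_surface_light(theta)
    ns = (y > CENSOR_LO) & (y < CENSOR_HI)
    if int(ns.sum()) < 3:
        return (
            np.zeros(b.shape[0]),
            np.ones(b.shape[0]),
            np.zeros(b.shape[0], dtype=bool),
        )
    slope, _, se, _ = interval_mle_fit(b, y, sigma=sigma_err)
    valid = np.isfinite(slope) & np.isfinite(se)
    slope = np.where(valid, slope, 0.0)
    se = np.where(valid, se, 1.0)
    return slope, se, valid


def _overlap_integral(meanlog, sdlog, z_hat, se, n_quad=N_QUAD):
    """Trapezoid integral of logNormal(Z) * Normal(Z; z_hat, se) over Z > 0."""
    z_hat = np.atleast_1d(np.asarray(z_hat, dtype=float))
    se = np.atleast_1d(np.asarray(se, dtype=float))
    # moment-matched normal envelope of the lognormal prior
    m1 = np.exp(meanlog + 0.5 * sdlog**2)
    s1 = max(m1 * np.sqrt(np.expm1(sdlog**2)), 1e-9)
    w1 = 1.0 / s1**2
    w2 = 1.0 / np.maximum(se, 1e-12) ** 2
    m = (m1 * w1 + z_hat * w2) / (w1 + w2)
    s = np.sqrt(1.0 / (w1 + w2))
    lo = np.maximum(1e-6, m - 6.0 * s)
    hi = np.maximum(m + 6.0 * s, lo + 1e-9)  # window above Z=0 even if Z_hat < 0
    u = np.linspace(0.0, 1.0, n_quad)
    z = lo[:, None] + (hi - lo)[:, None] * u[None, :]
    prior = np.exp(-0.5 * ((np.log(z) - meanlog) / sdlog) ** 2) / (
        z * sdlog * np.sqrt(2 * np.pi)
    )
    lik = np.exp(-0.5 * ((z - z_hat[:, None]) / se[:, None]) ** 2) / (
        se[:, None] * np.sqrt(2 * np.pi)
    )
    return np.trapezoid(prior * lik, z, axis=1)


def twilight_likelihood(tw, grid, params, floor_eps=FLOOR_EPS):
    """Spatial likelihood surface of one twilight over all grid nodes."""
    if tw.excluded:
        raise ValueError(f"twilight {tw.index} is excluded ({tw.reason})")
    n_nodes = grid.n_nodes
    raw = np.zeros(n_nodes)
    slope = se = valid = None
    if tw.n_samples >= 3:
        theta = solar_elevation_grid(grid.lon, grid.lat, tw.times)
        slope, se, valid = _batch_fit(theta, tw.log_light, sigma_err=None)
        meanlog = ageing_slope(params, tw.anchor_time)
        if np.any(valid):
            raw[valid] = _overlap_integral(
                meanlog, params.sdlog_Z, slope[valid], se[valid]
            )
    if not np.any(raw > 0):
        raise SurfaceError(f"twilight {tw.index}: template fit failed at every node")
    raw = np.maximum(raw, floor_eps * raw.max())
    w = raw / raw.sum()
    w = w / w.sum()  # second pass nails normalization to machine precision
    return LikelihoodSurface(
        tw.index, w, anchor_time=np.datetime64(tw.anchor_time, "s"), kind=tw.kind
    )


def build_surfaces(twilights, grid, params, floor_eps=FLOOR_EPS):
    """Surfaces for every usable twilight; returns (surfaces, exclusion log).

    Twilights already excluded, or failing at every node, are logged and
    skipped; surface order follows twilight order.
    """
    surfaces, excluded = [], []
    for tw in twilights:
        if tw.excluded:
            excluded.append((tw.index, tw.reason))
            continue
        try:
            surfaces.append(twilight_likelihood(tw, grid, params, floor_eps))
        except SurfaceError:
            tw.excluded = True
            tw.reason = "no-fit"
            excluded.append((tw.index, "no-fit"))
    return surfaces, excluded


def prefilter_outliers(twilights, window=11, threshold=4.0, scale_window=31):
    """Flag twilights whose terminator equator-crossing longitude jumps.

    Per twilight kind (rise and set are screened separately) the crossing
    longitudes are unwrapped, a centred running median (window 11) is
    subtracted, and residuals beyond ``threshold`` robust SDs (1.4826 x
    running MAD) are flagged.  The MAD uses a wider running window
    (``scale_window``) than the level: a short-window MAD is itself so
    noisy that the nominal threshold would misfire on a few percent of
    clean twilights.  Needs at least 20 twilights.
    """
    active = [tw for tw in twilights if not tw.excluded]
    if len(active) < 20:
        raise ValueError(f"need >= 20 twilights for the prefilter, have {len(active)}")
    flags = {id(tw): False for tw in twilights}
    for kind in ("rise", "set"):
        group = [tw for tw in active if tw.kind == kind]
        if len(group) < 3:
            continue
        x = np.array(
            [equator_crossing_longitude(tw.anchor_time, kind) for tw in group]
        )
        x = np.degrees(np.unwrap(np.radians(x)))
        med = _running_median(x, window)
        r = x - med
        mad = _running_median(np.abs(r), scale_window)
        sigma = 1.4826 * np.maximum(mad, 1e-3)
        for tw, flagged in zip(group, np.abs(r) / sigma > threshold):
            flags[id(tw)] = bool(flagged)
    return np.array([flags[id(tw)] for tw in twilights], dtype=bool)


def _running_median(x, window):
    half = window // 2
    n = x.size
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = np.median(x[lo:hi])
    return out


def surfaces_to_table(surfaces, min_weight=0.0):
    """Long-form (twilight_index, node_index, weight) array for export."""
    import pandas as pd

    rows = []
    for s in surfaces:
        keep = np.flatnonzero(s.weights > min_weight)
        rows.append(
            pd.DataFrame(
                {
                    "twilight_index": s.twilight_index,
                    "node_index": keep,
                    "weight": s.weights[keep],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
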