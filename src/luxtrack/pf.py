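"""Sequential importance resampling over twilights with block weighting.

Particles are node indices on the spatial grid.  Each twilight step:
propagate every particle through the two-state movement kernel, weight by
the twilight's likelihood surface (skipped for screened-out twilights),
zero the weight of sedentary particles sitting on nodes where settling is
masked, resample systematically, and record fixed-lag summaries.

Degeneracy control follows the block-sampling idea: the resampling weight of
a particle is exp(mean of its per-step log weights over the last ``block_n``
steps), carried along particle ancestry.  Positions ``block_n`` steps behind
the filter frontier are treated as final, so per-twilight posteriors are
fixed-lag smoothed marginals; with ``block_n = 1`` the scheme reduces to a
plain bootstrap filter and the reported filtering marginals converge to the
exact hidden-Markov forward recursion (the oracle used in tests).

If the recapture position is known, the final ``block_n`` states are
resampled with Gaussian weights on great-circle distance to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import bearing, gc_distance
from .movement import propose_steps

__all__ = [
    "RunConfig",
    "Posterior",
    "run_filter",
    "block_weights",
    "recapture_weights",
    "onthego_outlier",
    "weighted_quantile",
    "summarize",
    "monthly_stats",
]


@dataclass
class RunConfig:
    n_particles: int = 1_000_000
    block_n: int = 90
    recapture_sd: float = 25.0  # km
    outlier_angle: float = 100.0  # degrees; on-the-go turning-angle gate
    outlier_min_km: float = 150.0  # both legs must exceed this to be screened
    seed: int = 0
    resample: str = "systematic"
    ess_min: float = 10.0
    onthego: bool = True

    def __post_init__(self):
        if self.n_particles < 1000:
            raise ValueError("n_particles must be >= 1000")
        if self.block_n < 1:
            raise ValueError("block_n must be >= 1")
        if self.resample != "systematic":
            raise ValueError("only systematic resampling is implemented")


@dataclass
class Posterior:
    """Per-twilight posterior summaries from one filter run."""

    marginals: np.ndarray  # (T, n_nodes) fixed-lag smoothed node weights
    filtering: np.ndarray  # (T, n_nodes) filtered (pre-resample) node weights
    p_migration: np.ndarray  # (T,)
    dist_quartiles: np.ndarray  # (T, 3) km among migrating particles
    anchor_times: np.ndarray  # (T,) datetime64[s]
    kinds: list
    skipped: list  # (twilight_index, reason)
    grid: object = field(repr=False)
    sedentary_masked_weight: np.ndarray = None  # (T,) mass settling on masked habitat
    n_particles: int = 0
    seed: int = 0


def block_weights(log_weight_history):
    """Normalized resampling weights from per-step log-weight histories.

    ``log_weight_history`` has one row per particle and one column per
    stored step (at most ``block_n``); the weight is exp(row mean),
    renormalized across particles.  All--infinite histories get weight 0.
    """
    lw = np.asarray(log_weight_history, dtype=float)
    if lw.ndim == 1:
        lw = lw[:, None]
    if lw.shape[1] == 0:
        raise ValueError("history must contain at least one step")
    b = lw.mean(axis=1)
    m = np.max(b)
    if not np.isfinite(m):
        raise ValueError("all particle histories are impossible (-inf)")
    w = np.exp(b - m)
    return w / w.sum()


def recapture_weights(lons, lats, recapture, sd_km):
    """Gaussian weights on great-circle distance to the recapture point."""
    d = gc_distance((lons, lats), (recapture.lon, recapture.lat))
    d = np.atleast_1d(d)
    if d.min() > 6.0 * sd_km:
        raise RuntimeError(
            f"no particle within {6 * sd_km:.0f} km of the recapture point"
        )
    w = np.exp(-0.5 * (d / sd_km) ** 2)
    return w / w.sum()


def onthego_outlier(pos_prev, pos_tentative, pos_next, angle_deg=100.0, min_km=150.0):
    """Is the middle twilight an on-the-go outlier (out-and-back excursion)?

    ``pos_prev`` is the filtered ensemble mean before the step (position A),
    ``pos_tentative`` the likelihood-weighted mean of the proposed particles
    under the current surface (B), and ``pos_next`` the centroid of the next
    twilight's surface (C, the one-step lookahead).  The twilight is an
    outlier when both legs are substantial, the return leg is no longer than
    the outbound one, the track actually returns (C lands back near A -- a
    genuine one-way arrival has C far from A and must never be discarded),
    and the turning angle at B (angle between the directions back to A and
    on to C; 0 for a perfect out-and-back, 180 for straight-line travel) is
    below ``angle_deg``.  The minimum-leg gate keeps sub-grid-scale jitter
    of surface centroids from triggering flags on stationary animals.
    """
    A, B, C = pos_prev, pos_tentative, pos_next
    d1, d2 = gc_distance(B, A), gc_distance(B, C)
    if d1 < min_km or d2 < min_km or d2 > d1 or gc_distance(A, C) > min_km:
        return False
    turn = abs((bearing(B, A) - bearing(B, C) + 180.0) % 360.0 - 180.0)
    return bool(turn < angle_deg)


def _systematic_resample(w, rng, n):
    positions = (rng.random() + np.arange(n)) / n
    return np.searchsorted(np.cumsum(w), positions).clip(max=w.size - 1)


def run_filter(surfaces, prior, grid, release, cfg, recapture=None):
    """Run the particle filter over time-ordered twilight surfaces.

    ``release`` (and optionally ``recapture``) are GeoPositions; particles
    start at the node nearest the release point.  Reproducible given
    ``cfg.seed``.
    """
    T = len(surfaces)
    if T == 0:
        raise ValueError("no surfaces to filter")
    n = cfg.n_particles
    n_nodes = grid.n_nodes
    rng = np.random.default_rng(cfg.seed)
    logw_surface = [np.log(s.weights) for s in surfaces]

    # surface centroids provide the one-step lookahead of the outlier screen
    W = np.array([s.weights for s in surfaces])
    zx = W @ np.cos(np.radians(grid.lon))
    zy = W @ np.sin(np.radians(grid.lon))
    cen_lon = np.degrees(np.arctan2(zy, zx))
    cen_lat = W @ grid.lat
    skipped = [(s.twilight_index, "prefilter") for s in surfaces if s.flagged_outlier]

    release_node = grid.nearest_usable(release.lon, release.lat)
    H = np.empty((n, T + 1), dtype=np.int32)
    H[:, 0] = release_node
    LW = np.zeros((n, cfg.block_n))
    cur = np.full(n, release_node, dtype=np.int64)

    marginals = np.zeros((T, n_nodes))
    filtering = np.zeros((T, n_nodes))
    p_mig = np.zeros(T)
    sed_masked = np.zeros(T)
    dist_q = np.full((T, 3), np.nan)
    mask_stat = grid.mask_stationary

    def snapshot(j):
        frm, to = H[:, j].astype(np.int64), H[:, j + 1].astype(np.int64)
        marginals[j] = np.bincount(to, minlength=n_nodes) / n
        moved = frm != to
        p_mig[j] = moved.mean()
        sed_masked[j] = (~moved & ~mask_stat[to]).mean()
        if np.any(moved):
            d = gc_distance(
                (grid.lon[frm[moved]], grid.lat[frm[moved]]),
                (grid.lon[to[moved]], grid.lat[to[moved]]),
            )
            dist_q[j] = np.quantile(np.atleast_1d(d), [0.25, 0.5, 0.75])

    def _mean_pos(nodes, w=None):
        x = np.cos(np.radians(grid.lon[nodes]))
        yy = np.sin(np.radians(grid.lon[nodes]))
        if w is None:
            lon = np.degrees(np.arctan2(yy.mean(), x.mean()))
            lat = grid.lat[nodes].mean()
        else:
            lon = np.degrees(np.arctan2(w @ yy, w @ x))
            lat = w @ grid.lat[nodes]
        return float(lon), float(lat)

    for i in range(T):
        prev_mean = _mean_pos(cur)
        new_nodes, moved, _, _ = propose_steps(cur, prior, grid, rng)
        skip = surfaces[i].flagged_outlier
        if cfg.onthego and not skip and 1 <= i <= T - 2:
            wt = surfaces[i].weights[new_nodes]
            tot = wt.sum()
            if tot > 0:
                tent_mean = _mean_pos(new_nodes, wt / tot)
                if onthego_outlier(
                    prev_mean,
                    tent_mean,
                    (cen_lon[i + 1], cen_lat[i + 1]),
                    cfg.outlier_angle,
                    cfg.outlier_min_km,
                ):
                    skip = True
                    skipped.append((surfaces[i].twilight_index, "on-the-go"))
        lw = np.zeros(n) if skip else logw_surface[i][new_nodes].copy()
        lw[~moved & ~mask_stat[new_nodes]] = -np.inf  # settling on masked habitat
        LW[:, i % cfg.block_n] = lw
        m = min(i + 1, cfg.block_n)
        cols = LW[:, :m] if i + 1 <= cfg.block_n else LW
        try:
            w = block_weights(cols)
        except ValueError as exc:
            raise RuntimeError(
                f"particle filter collapsed at twilight {surfaces[i].twilight_index}: {exc}"
            ) from exc
        filtering[i] = np.bincount(new_nodes, weights=w, minlength=n_nodes)
        ess = 1.0 / np.sum(w**2)
        if ess < cfg.ess_min:
            raise RuntimeError(
                f"effective sample size {ess:.1f} < {cfg.ess_min} at twilight "
                f"{surfaces[i].twilight_index}"
            )
        A = _systematic_resample(w, rng, n)
        H[:, : i + 2] = H[A, : i + 2]
        LW = LW[A]
        cur = new_nodes[A]
        H[:, i + 1] = cur
        j = i - cfg.block_n
        if j >= 0:
            snapshot(j)

    if recapture is not None:
        wr = recapture_weights(grid.lon[cur], grid.lat[cur], recapture, cfg.recapture_sd)
        A = _systematic_resample(wr, rng, n)
        H = H[A]

    for j in range(max(0, T - cfg.block_n), T):
        snapshot(j)

    return Posterior(
        marginals=marginals,
        filtering=filtering,
        p_migration=p_mig,
        dist_quartiles=dist_q,
        anchor_times=np.array([s.anchor_time for s in surfaces], dtype="datetime64[s]"),
        kinds=[s.kind for s in surfaces],
        skipped=skipped,
        grid=grid,
        sedentary_masked_weight=sed_masked,
        n_particles=n,
        seed=cfg.seed,
    )


def exact_filter_marginals(surfaces, transition, release_node):
    """Exact hidden-Markov forward-filter marginals on a small grid.

    ``transition`` is the row-stochastic single-step matrix; the recursion
    alpha_i proportional to (transition^T alpha_{i-1}) * L_i starts from a point
    mass at ``release_node``.  Independent of the particle filter; used as
    its convergence oracle.  Returns an array of shape (T, n_nodes).
    """
    n = transition.shape[0]
    alpha = np.zeros(n)
    alpha[release_node] = 1.0
    out = np.zeros((len(surfaces), n))
    for i, s in enumerate(surfaces):
        alpha = transition.T @ alpha
        if not s.flagged_outlier:
            alpha = alpha * s.weights
        total = alpha.sum()
        if total <= 0:
            raise RuntimeError(f"forward filter vanished at twilight {i}")
        alpha /= total
        out[i] = alpha
    return out


def weighted_quantile(values, weights, q):
    """Midpoint-interpolated inverse-CDF weighted quantiles.

    Interpolation knots sit at (cumulative weight - w/2) / total, so two
    equal-weight values give median halfway between them and quartiles at
    the values themselves.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    keep = weights > 0
    values, weights = values[keep], weights[keep]
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w) - 0.5 * w
    return np.interp(np.asarray(q, dtype=float), cum / w.sum(), v)


def _lon_quantiles(lons, weights, q):
    ref = lons[np.argmax(weights)]
    rel = (lons - ref + 180.0) % 360.0 - 180.0
    out = ref + weighted_quantile(rel, weights, q)
    return (out + 180.0) % 360.0 - 180.0


QS = (0.025, 0.25, 0.5, 0.75, 0.975)
_QLABEL = {0.025: "q025", 0.25: "q25", 0.5: "median", 0.75: "q75", 0.975: "q975"}


def summarize(posterior, truth=None):
    """Per-twilight summary table of the posterior.

    Columns: anchor time and kind; weighted quantiles (2.5/25/50/75/97.5%)
    of longitude and latitude; migration probability; distance quartiles of
    migrating particles; whether the twilight's surface was skipped.  If
    ``truth`` (a DataFrame with lon/lat per twilight, aligned by row) is
    given, error columns (estimated minus true) are added.
    """
    grid = posterior.grid
    skipped_idx = {i for i, _ in posterior.skipped}
    rows = []
    for j in range(posterior.marginals.shape[0]):
        w = posterior.marginals[j]
        lat_q = weighted_quantile(grid.lat, w, QS)
        lon_q = _lon_quantiles(grid.lon, w, QS)
        rows.append(
            {
                "time": posterior.anchor_times[j],
                "kind": posterior.kinds[j],
                **{f"lon_{_QLABEL[q]}": v for q, v in zip(QS, lon_q)},
                **{f"lat_{_QLABEL[q]}": v for q, v in zip(QS, lat_q)},
                "p_migration": posterior.p_migration[j],
                "dist_q25": posterior.dist_quartiles[j, 0],
                "dist_q50": posterior.dist_quartiles[j, 1],
                "dist_q75": posterior.dist_quartiles[j, 2],
                "skipped": j in skipped_idx,
            }
        )
    out = pd.DataFrame(rows)
    if truth is not None:
        out["lat_error"] = out["lat_median"].to_numpy() - np.asarray(truth["lat"])
        dlon = out["lon_median"].to_numpy() - np.asarray(truth["lon"])
        out["lon_error"] = (dlon + 180.0) % 360.0 - 180.0
    return out


def monthly_stats(summary):
    """Monthly mean bias and SD of the error columns of a summary table."""
    if "lat_error" not in summary:
        raise ValueError("summary has no error columns; pass truth to summarize()")
    df = summary.copy()
    df["month"] = pd.to_datetime(df["time"]).dt.month
    g = df.groupby("month")
    return pd.DataFrame(
        {
            "bias_lat": g["lat_error"].mean(),
            "sd_lat": g["lat_error"].std(ddof=1),
            "bias_lon": g["lon_error"].mean(),
            "sd_lon": g["lon_error"].std(ddof=1),
            "n": g.size(),
        }
    )
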