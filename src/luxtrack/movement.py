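"""Two-state movement kernel: sedentary with probability 1 - p_move, else a
migratory step with von Mises direction and truncated-normal length.

Steps are uncorrelated between twilights (no velocity state): direction,
distance and the behavioural switch are drawn afresh each interval, which
suits passerine migration where successive nights are nearly independent.
Proposed destinations are snapped to the nearest usable grid node.  A draw
that snaps back onto the origin, or that falls outside every node's cell
(beyond 3/4 of the node spacing from its nearest node, i.e. off the study
region), is redrawn (up to 10 times, then the particle stays put): the
walk is thereby confined to the gridded state space, so that "no movement
shorter than a_trunc" keeps its meaning on a 50-km grid and the sampled
kernel agrees with the exact cell-to-cell transition matrix.

``transition_matrix`` provides the exact single-step kernel on small grids,
used as an independent oracle for the particle filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import i0, ndtr, ndtri

from .grid import bearing, destination, gc_distance

__all__ = [
    "MovementPrior",
    "Transition",
    "draw_steps",
    "propose_step",
    "propose_steps",
    "transition_matrix",
    "truncnorm_moments",
]


@dataclass
class MovementPrior:
    """Priors of the two-state random walk.

    p_move: per-twilight probability of the migrating state.
    mu_dir/kappa: von Mises direction prior, degrees from north; kappa = 0 is
        uniform (no preferred direction).
    mu_dist/sigma_dist: truncated-normal step length, km.
    a_trunc/b_trunc: hard bounds on a single between-twilight flight, km.
    """

    p_move: float = 0.1
    mu_dir: float = 0.0
    kappa: float = 0.0
    mu_dist: float = 300.0
    sigma_dist: float = 150.0
    a_trunc: float = 45.0
    b_trunc: float = 1500.0

    def __post_init__(self):
        if not 0.0 <= self.p_move < 1.0:
            raise ValueError("p_move must be in [0, 1)")
        if not 0.0 < self.a_trunc < self.b_trunc:
            raise ValueError("need 0 < a_trunc < b_trunc")
        if self.mu_dist <= 0 or self.sigma_dist <= 0:
            raise ValueError("mu_dist and sigma_dist must be positive")
        if self.kappa < 0:
            raise ValueError("kappa must be nonnegative")


@dataclass
class Transition:
    from_node: int
    to_node: int
    state: str  # "sedentary" | "migrating"
    distance: float
    direction: float


def draw_steps(prior, n, rng):
    """Raw (distance, direction) draws for ``n`` migratory steps.

    Distances by inverse-CDF truncated-normal sampling, directions from the
    von Mises prior (uniform when kappa = 0).
    """
    alpha = (prior.a_trunc - prior.mu_dist) / prior.sigma_dist
    beta = (prior.b_trunc - prior.mu_dist) / prior.sigma_dist
    fa, fb = ndtr(alpha), ndtr(beta)
    u = fa + (fb - fa) * rng.random(n)
    dist = prior.mu_dist + prior.sigma_dist * ndtri(u)
    dist = np.clip(dist, prior.a_trunc, prior.b_trunc)
    if prior.kappa == 0:
        direc = rng.random(n) * 360.0
    else:
        direc = (
            np.degrees(rng.vonmises(np.radians(prior.mu_dir), prior.kappa, n)) % 360.0
        )
    return dist, direc


def propose_steps(nodes, prior, grid, rng, max_redraw=10):
    """Vectorized one-step proposal for particles at ``nodes``.

    Returns (new_nodes, moved, distance, direction): realized node-to-node
    values; sedentary entries have distance 0 and direction NaN.
    """
    nodes = np.asarray(nodes)
    n = nodes.size
    new_nodes = nodes.copy()
    moving = rng.random(n) < prior.p_move
    pending = np.flatnonzero(moving)
    snap_tol = 0.75 * grid.spacing_km
    for _ in range(max_redraw):
        if pending.size == 0:
            break
        dist, direc = draw_steps(prior, pending.size, rng)
        dlon, dlat = destination(
            grid.lon[nodes[pending]], grid.lat[nodes[pending]], direc, dist
        )
        snapped = grid.nearest_usable(dlon, dlat)
        snap_d = gc_distance(
            (dlon, dlat), (grid.lon[snapped], grid.lat[snapped])
        )
        ok = (snapped != nodes[pending]) & (np.atleast_1d(snap_d) <= snap_tol)
        new_nodes[pending[ok]] = snapped[ok]
        pending = pending[~ok]
    # redraws exhausted: those particles stay (sedentary this step)
    moved = new_nodes != nodes
    distance = np.zeros(n)
    direction = np.full(n, np.nan)
    if np.any(moved):
        a = (grid.lon[nodes[moved]], grid.lat[nodes[moved]])
        b = (grid.lon[new_nodes[moved]], grid.lat[new_nodes[moved]])
        distance[moved] = gc_distance(a, b)
        direction[moved] = bearing(a, b)
    return new_nodes, moved, distance, direction


def propose_step(node, prior, grid, rng):
    """Single-particle proposal; see :func:`propose_steps`."""
    new, moved, dist, direc = propose_steps(np.array([node]), prior, grid, rng)
    if moved[0]:
        return Transition(int(node), int(new[0]), "migrating", float(dist[0]), float(direc[0]))
    return Transition(int(node), int(node), "sedentary", 0.0, 0.0)


def _truncnorm_pdf(x, mu, sigma, a, b):
    z = (x - mu) / sigma
    alpha, beta = (a - mu) / sigma, (b - mu) / sigma
    norm = ndtr(beta) - ndtr(alpha)
    pdf = np.exp(-0.5 * z**2) / (sigma * np.sqrt(2 * np.pi) * norm)
    return np.where((x >= a) & (x <= b), pdf, 0.0)


def truncnorm_moments(mu, sigma, a, b):
    """Mean and SD of the truncated normal (closed form)."""
    alpha, beta = (a - mu) / sigma, (b - mu) / sigma
    phi = lambda z: np.exp(-0.5 * z**2) / np.sqrt(2 * np.pi)
    Z = ndtr(beta) - ndtr(alpha)
    mean = mu + sigma * (phi(alpha) - phi(beta)) / Z
    var = sigma**2 * (
        1
        + (alpha * phi(alpha) - beta * phi(beta)) / Z
        - ((phi(alpha) - phi(beta)) / Z) ** 2
    )
    return mean, np.sqrt(var)


def transition_matrix(grid, prior, max_nodes=2000):
    """Exact row-stochastic single-step kernel on a small grid.

    M[k, l] = (1 - p_move) 1[k = l] + p_move q(k -> l), where q is the
    probability that a migratory draw (truncated-normal step length, von
    Mises direction) lands in node l's cell: the planar displacement density
    p_S(d) p_Phi(brg) / d (polar Jacobian) integrated over the
    (equal-area) cell and renormalized over reachable nodes.  Rows with no
    reachable destination put all mass on staying.
    """
    n = grid.n_nodes
    if n > max_nodes:
        raise ValueError(f"grid has {n} nodes; transition_matrix supports <= {max_nodes}")
    lon, lat = grid.lon, grid.lat
    d = gc_distance((lon[:, None], lat[:, None]), (lon[None, :], lat[None, :]))
    brg = bearing((lon[:, None], lat[:, None]), (lon[None, :], lat[None, :]))
    q = _truncnorm_pdf(d, prior.mu_dist, prior.sigma_dist, prior.a_trunc, prior.b_trunc)
    q = q / np.maximum(d, 1.0)  # polar-to-planar Jacobian at the cell centre
    if prior.kappa > 0:
        ang = np.radians(brg - prior.mu_dir)
        q = q * np.exp(prior.kappa * np.cos(ang)) / (2 * np.pi * i0(prior.kappa))
    q[:, ~grid.mask_any] = 0.0
    np.fill_diagonal(q, 0.0)
    row = q.sum(axis=1)
    reachable = row > 0
    q[reachable] /= row[reachable, None]
    M = prior.p_move * q
    diag = np.where(reachable, 1.0 - prior.p_move, 1.0)
    M[np.arange(n), np.arange(n)] += diag
    return M
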