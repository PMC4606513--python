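"""Per-twilight template fits at a known site and pooling into a slope prior.

At a known calibration position every twilight yields an ordinary least
squares fit of observed log light on the template value f''(theta), giving a
slope estimate with standard error, an intercept (tag offset plus that
twilight's attenuation -- not separately identifiable and not needed), and a
residual SD.  Pooling the retained slopes gives the tag's lognormal slope
distribution Z ~ logNormal(meanlog_Z, sdlog_Z) and the residual noise scale
sigma_err used by the positional likelihood.

The lognormal may be specified on either scale: ``natural-scale`` means the
quoted centre/spread are for Z itself (mapped by the delta method,
meanlog = log(centre), sdlog = spread/centre); ``log-scale`` means they are
the log-slope mean and SD directly.  The ``parameterization`` tag records
which reading produced the stored fields.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .solar import solar_elevation
from .template import log_surface_light

__all__ = [
    "FitError",
    "CalibrationError",
    "TwilightFit",
    "CalibrationParams",
    "fit_twilight_slope",
    "calibrate",
    "ageing_slope",
]

SDLOG_FLOOR = 1e-3  # keeps the slope prior a proper density on clean data


class FitError(ValueError):
    """A twilight cannot be fit at this position (too few samples or flat design)."""


class CalibrationError(ValueError):
    """Not enough usable twilight fits to pool a calibration."""


@dataclass
class TwilightFit:
    Z_hat: float
    sigma_Z: float
    a_hat: float
    resid_sd: float
    n_samples: int


@dataclass
class CalibrationParams:
    meanlog_Z: float
    sdlog_Z: float
    sigma_err: float
    ageing: tuple | None = None  # (meanlog_Z_start, meanlog_Z_end, t_start, t_end)
    parameterization: str = "log-scale"
    n_fits: int | None = None  # twilights pooled; None = centre treated as exact

    @property
    def meanlog_se(self):
        """Standard error of the calibrated log-slope centre (None if the
        centre is to be treated as exact, e.g. externally supplied priors)."""
        if not self.n_fits:
            return None
        return self.sdlog_Z / np.sqrt(self.n_fits)

    def __post_init__(self):
        if self.sdlog_Z <= 0:
            raise ValueError("sdlog_Z must be positive")
        if self.sigma_err <= 0:
            raise ValueError("sigma_err must be positive")

    @classmethod
    def from_natural(cls, center, spread, sigma_err, ageing=None):
        """Lognormal slope prior quoted on the natural scale (delta method)."""
        if center <= 0:
            raise ValueError("natural-scale slope center must be positive")
        return cls(
            meanlog_Z=float(np.log(center)),
            sdlog_Z=max(spread / center, SDLOG_FLOOR),
            sigma_err=sigma_err,
            ageing=ageing,
            parameterization="natural-scale",
        )

    @property
    def natural_center(self):
        """Median of the slope distribution on the natural scale."""
        return float(np.exp(self.meanlog_Z))


# The device quantizes light to integers and clips the scale at both ends,
# so a stored value l in 1..63 means the underlying log reading lies in
# [log(l - 1/2), log(l + 1/2)], a saturated 64 means it lies above
# log(63.5), and a dark 0 means it lies below log(0.5).  Fitting the
# regression by interval likelihood -- every sample contributes
# P(y in its interval) -- is free of the flat-slope selection bias that
# plain least squares on log(l) suffers at the clipped ends, because the
# samples are independent and every interval probability is exact.  The
# MLE is computed by EM with truncated-normal conditional moments.
CENSOR_HI = float(np.log(63.5))
CENSOR_LO = float(np.log(0.5) + 1e-9)  # stored value of dark records
_SIGMA_FLOOR = 0.05
_N_EM_ITER = 8


def _norm_pdf(x):
    return np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)


def interval_moments(mu, sigma, lo, hi):
    """Conditional mean and variance of y ~ Normal(mu, sigma) given
    y in [lo, hi]; ``lo`` may be -inf and ``hi`` +inf (censored samples).

    Where the interval carries essentially no mass under (mu, sigma) the
    conditional mean falls back to the interval midpoint (or one noise SD
    beyond its finite edge), which keeps the EM update finite at grossly
    wrong positions.
    """
    from scipy.special import ndtr

    sigma = np.broadcast_to(sigma, np.broadcast_shapes(np.shape(mu), np.shape(sigma)))
    lo_inf = np.isinf(lo)
    hi_inf = np.isinf(hi)
    al = np.where(lo_inf, -np.inf, (lo - mu) / sigma)
    be = np.where(hi_inf, np.inf, (hi - mu) / sigma)
    pa = np.where(lo_inf, 0.0, _norm_pdf(al))
    pb = np.where(hi_inf, 0.0, _norm_pdf(be))
    D = ndtr(be) - ndtr(al)
    ok = D > 1e-12
    Ds = np.where(ok, D, 1.0)
    r1 = (pa - pb) / Ds
    al_f = np.where(lo_inf | ~ok, 0.0, al)  # avoid inf*0 in the products
    be_f = np.where(hi_inf | ~ok, 0.0, be)
    r2 = (al_f * pa - be_f * pb) / Ds
    mean = mu + sigma * r1
    var = sigma**2 * np.maximum(1.0 + r2 - r1**2, 1e-12)
    fallback = np.where(
        hi_inf, lo + sigma, np.where(lo_inf, hi - sigma, 0.5 * (lo + hi))
    )
    mean = np.where(ok, mean, fallback)
    var = np.where(ok, var, sigma**2)
    return mean, var


def sample_intervals(y):
    """Quantization interval (lo, hi) on the log axis for stored samples."""
    y = np.asarray(y, dtype=float)
    level = np.round(np.exp(y))
    dark = y <= CENSOR_LO
    sat = y >= CENSOR_HI
    lo = np.where(sat, CENSOR_HI, np.where(dark, -np.inf, np.log(np.maximum(level - 0.5, 0.5))))
    hi = np.where(dark, float(np.log(0.5)), np.where(sat, np.inf, np.log(np.maximum(level, 1.0) + 0.5)))
    return lo, hi


def interval_mle_fit(b, y, sigma=None, n_iter=_N_EM_ITER):
    """Interval-likelihood regression of quantized log light on the template.

    ``b`` has shape (n_fits, n_samples) -- one row per candidate position --
    and ``y`` (n_samples,) holds log device readings (dark records stored at
    log(1/2), saturated at the clip value).  Returns arrays (slope,
    intercept, se, sigma_hat) of length n_fits.

    The slope/intercept are maximum-interval-likelihood estimates found by
    Fisher scoring: per-sample scores of the interval probability and the
    observed information from Louis' identity (complete information 1/sigma^2
    minus the conditional variance of the missing reading).  When ``sigma``
    is None the noise SD is profiled alongside by an EM second-moment
    update; passing the calibrated residual SD instead pins the noise scale
    and speeds convergence (the node-fit hot path).  Standard errors come
    from the inverse observed-information matrix.
    """
    b = np.atleast_2d(np.asarray(b, dtype=float))
    y = np.asarray(y, dtype=float)
    lo, hi = sample_intervals(y)
    lo_inf, hi_inf = np.isinf(lo), np.isinf(hi)

    mid = (y > CENSOR_LO) & (y < CENSOR_HI)
    bn, yn = b[:, mid], y[mid]
    bm = bn.mean(axis=1, keepdims=True)
    sxx0 = np.einsum("ij,ij->i", bn - bm, bn - bm)
    sxx0 = np.where(sxx0 > 1e-12, sxx0, np.nan)
    Z = ((bn - bm) @ (yn - yn.mean())) / sxx0
    A = yn.mean() - Z * bm[:, 0]

    free_sigma = sigma is None
    sg = np.full(b.shape[0], 0.32) if free_sigma else np.broadcast_to(
        np.asarray(sigma, dtype=float), (b.shape[0],)
    ).copy()
    from scipy.special import ndtr

    S0 = S1 = S2 = det = None
    for _ in range(n_iter):
        mu = A[:, None] + Z[:, None] * b
        s = sg[:, None]
        al = np.where(lo_inf, -8.0, np.clip((lo - mu) / s, -8.0, 8.0))
        be = np.where(hi_inf, 8.0, np.clip((hi - mu) / s, -8.0, 8.0))
        pa = np.where(lo_inf, 0.0, _norm_pdf(al))
        pb = np.where(hi_inf, 0.0, _norm_pdf(be))
        D = np.clip(ndtr(be) - ndtr(al), 1e-12, None)
        r1 = (pa - pb) / D
        r2 = (np.where(lo_inf, 0.0, al * pa) - np.where(hi_inf, 0.0, be * pb)) / D
        var_frac = np.clip(1.0 + r2 - r1**2, 1e-6, 1.0)
        score = r1 / s
        k = np.clip(1.0 - var_frac, 1e-4, None) / s**2
        S0 = k.sum(axis=1)
        S1 = np.einsum("ij,ij->i", k, b)
        S2 = np.einsum("ij,ij->i", k, b * b)
        g0 = score.sum(axis=1)
        g1 = np.einsum("ij,ij->i", score, b)
        det = np.clip(S0 * S2 - S1 * S1, 1e-12, None)
        A = A + np.clip((S2 * g0 - S1 * g1) / det, -2.0, 2.0)
        Z = Z + np.clip((S0 * g1 - S1 * g0) / det, -0.2, 0.2)
        if free_sigma:
            sg = np.maximum(
                sg * np.sqrt(np.mean(r1**2 + var_frac, axis=1)), _SIGMA_FLOOR
            )
    se = np.sqrt(S0 / det)
    if free_sigma:
        # profile-likelihood sigma is biased low; rescale by the
        # information-weighted effective sample count (censored samples
        # carry only a fraction of a sample's worth of information) with
        # the usual two-parameter degrees-of-freedom correction
        n_eff = np.sum(1.0 - var_frac, axis=1)
        sg = sg * np.sqrt(n_eff / np.maximum(n_eff - 2.0, 1.0))
    return Z, A, se, sg


def fit_twilight_slope(tw, pos):
    """Interval-likelihood fit of a twilight's quantized log light on the
    template at position ``pos``."""
    if tw.n_samples < 3:
        raise FitError(f"twilight {tw.index}: need >= 3 samples, have {tw.n_samples}")
    theta = solar_elevation(pos, tw.times)
    b = log_surface_light(theta)
    y = tw.log_light
    mid = (y > CENSOR_LO) & (y < CENSOR_HI)
    if mid.sum() < 3:
        raise FitError(f"twilight {tw.index}: fewer than 3 unclipped samples")
    bm = b[mid].mean()
    if np.sum((b[mid] - bm) ** 2) < 1e-12:
        raise FitError(f"twilight {tw.index}: no template variation at this position")
    slope, intercept, se, sigma = interval_mle_fit(b[None, :], y, n_iter=25)
    if not np.isfinite(slope[0]):
        raise FitError(f"twilight {tw.index}: degenerate design")
    return TwilightFit(
        Z_hat=float(slope[0]),
        sigma_Z=float(se[0]) if se[0] > 0 else SDLOG_FLOOR * 1e-3,
        a_hat=float(intercept[0]),
        resid_sd=float(sigma[0]),
        n_samples=tw.n_samples,
    )


def calibrate(fits, drop_rule=None):
    """Pool twilight fits from a known site into calibration parameters.

    Non-positive slopes are physically impossible under the template model
    and are dropped; ``drop_rule`` (fit -> bool, true = drop) can remove
    further fits.  Requires at least 10 retained fits (~5 days of twilights).
    Log-slope mean and SD come from the method of moments on log Z_hat;
    sigma_err is the root mean square of the per-twilight residual SDs.
    """
    kept = [f for f in fits if f.Z_hat > 0 and not (drop_rule and drop_rule(f))]
    if len(kept) < 10:
        raise CalibrationError(
            f"only {len(kept)} usable twilight fits; need >= 10 (about 5 days)"
        )
    logz = np.log([f.Z_hat for f in kept])
    sdlog = float(np.std(logz, ddof=1))
    sigma_err = float(np.sqrt(np.mean([f.resid_sd**2 for f in kept])))
    return CalibrationParams(
        meanlog_Z=float(np.mean(logz)),
        sdlog_Z=max(sdlog, SDLOG_FLOOR),
        sigma_err=max(sigma_err, 1e-6),
        parameterization="log-scale",
        n_fits=len(kept),
    )


def ageing_slope(params, t):
    """Log-slope mean at time ``t`` under the linear tag-ageing model."""
    if params.ageing is None:
        return params.meanlog_Z
    m0, m1, t0, t1 = params.ageing
    t0 = np.datetime64(t0, "s")
    t1 = np.datetime64(t1, "s")
    t = np.datetime64(t, "s")
    if t1 <= t0:
        return m0
    if t < t0 or t > t1:
        warnings.warn("time outside deployment; clamping ageing interpolation")
        t = min(max(t, t0), t1)
    frac = (t - t0) / (t1 - t0)
    return float(m0 + frac * (m1 - m0))
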