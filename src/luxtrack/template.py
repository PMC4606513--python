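"""The irradiance template: solar angle -> log surface light -> log tag reading.

Surface irradiance during twilight follows a fixed, shading-independent curve

    f''(theta) = -u^2 - log(erfc(u)),    u = 21.5 * sin(theta),

with theta the geometric solar elevation.  A tag reads light linearly on the
log scale, ``log ELM = intercept + Z * f''(theta)``, where the slope ``Z`` is a
tag property and the intercept absorbs the tag offset together with the
per-twilight attenuation (clouds, vegetation, posture).  Because attenuation
is multiplicative, it moves only the intercept; the slope against the known
curve is what carries positional information.

Numerics: ``erfc(u)`` underflows for u around 21.5 (~1e-203), so the template
is evaluated through the scaled complementary error function via the identity
``log erfc(u) = -u^2 + log erfcx(u)``, which collapses f'' to
``-log(erfcx(u))`` -- finite and well-conditioned over the whole domain.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erfcx
from scipy.optimize import brentq

__all__ = [
    "template_u",
    "log_surface_light",
    "expected_log_light",
    "invert_expected_log_light",
]

_COEF = 21.5


def _check_theta(theta):
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < -90.0) or np.any(theta > 90.0):
        raise ValueError("solar angle outside [-90, 90] degrees")
    return theta


def template_u(theta):
    """u = 21.5 * sin(theta); theta in degrees, |theta| <= 90."""
    theta = _check_theta(theta)
    out = _COEF * np.sin(np.radians(theta))
    return float(out) if np.ndim(out) == 0 else out


def log_surface_light(theta):
    """Template log irradiance f''(theta) = -u^2 - log(erfc(u)) = -log(erfcx(u)).

    Strictly increasing on [-90, 90] with f''(0) = 0.
    """
    theta = _check_theta(theta)
    out = -np.log(erfcx(_COEF * np.sin(np.radians(theta))))
    return float(out) if np.ndim(out) == 0 else out


def expected_log_light(theta, Z, intercept):
    """Expected log tag reading ``intercept + Z * f''(theta)``; requires Z > 0."""
    if np.any(np.asarray(Z) <= 0):
        raise ValueError("slope Z must be positive")
    out = intercept + Z * log_surface_light(theta)
    return float(out) if np.ndim(out) == 0 else out


def invert_expected_log_light(log_light, Z, intercept, lo=-90.0, hi=90.0):
    """Solar angle at which the expected log reading equals ``log_light``.

    f'' is strictly monotone so the root is unique; bisection on [lo, hi].
    Raises ValueError when the target is outside the attainable range.
    """
    if Z <= 0:
        raise ValueError("slope Z must be positive")
    target = (log_light - intercept) / Z

    def g(th):
        return log_surface_light(th) - target

    if g(lo) > 0 or g(hi) < 0:
        raise ValueError("log_light outside attainable range on [lo, hi]")
    return brentq(g, lo, hi, xtol=1e-10)
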