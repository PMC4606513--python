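import numpy as np
import pytest

from luxtrack import CalibrationParams, GeoPosition, TwilightData, make_grid
from luxtrack.solar import solar_elevation
from luxtrack.template import log_surface_light


@pytest.fixture(scope="session")
def default_params():
    return CalibrationParams.from_natural(center=0.23, spread=0.01, sigma_err=0.32)


@pytest.fixture(scope="session")
def small_grid():
    return make_grid(GeoPosition(0.0, 40.0), 450.0, 50.0)


def synth_twilight(
    pos,
    date="2011-01-15",
    kind="rise",
    Z=0.23,
    intercept=6.14,
    sigma=0.32,
    rng=None,
    interval_s=120,
    index=0,
    quantize=True,
):
    """Synthetic twilight built directly from the irradiance template.

    Samples every ``interval_s`` over a window around the time the expected
    reading crosses mid-scale, mimicking what assembly produces from a real
    series (quantized readings, dark stored at log(1/2), clip at 64).
    """
    rng = rng or np.random.default_rng(0)
    t0 = np.datetime64(f"{date}T00:00:00")
    ts = t0 + np.arange(0, 43200 if kind == "rise" else 86400, interval_s).astype(
        "timedelta64[s]"
    )
    if kind == "set":
        ts = ts[ts >= t0 + np.timedelta64(12, "h")]
    theta = solar_elevation(pos, ts)
    y = intercept + Z * log_surface_light(theta) + rng.normal(0, sigma, ts.size)
    light = np.clip(np.round(np.exp(np.minimum(y, 10.0))), 0, 64).astype(int)
    if kind == "rise":
        anchor_idx = int(np.argmax(light >= 32))
    else:
        anchor_idx = int(len(light) - 1 - np.argmax(light[::-1] >= 32))
    anchor = np.datetime64(ts[anchor_idx], "s")
    keep = (np.abs((ts - anchor) / np.timedelta64(1, "m")) <= 90) & (theta > -25)
    log_light = np.where(light == 0, float(np.log(0.5)), np.log(np.maximum(light, 0.5)))
    if not quantize:
        log_light = y
    return TwilightData(index, kind, anchor, ts[keep], log_light[keep])
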