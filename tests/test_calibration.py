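import warnings

import numpy as np
import pytest

from luxtrack import (
    CalibrationError,
    CalibrationParams,
    FitError,
    GeoPosition,
    TwilightData,
    ageing_slope,
    calibrate,
    fit_twilight_slope,
)
from luxtrack.calibration import TwilightFit, interval_mle_fit

from conftest import synth_twilight

SITE = GeoPosition(0.0, 5.0)


class TestFitTwilightSlope:
    def test_noise_free_recovery_to_quantization_precision(self):
        tw = synth_twilight(SITE, sigma=1e-9)
        fit = fit_twilight_slope(tw, SITE)
        # readings are integer device units, so recovery is exact only up to
        # the quantization interval
        assert fit.Z_hat == pytest.approx(0.23, abs=5e-3)
        assert fit.resid_sd < 0.1
        assert fit.a_hat == pytest.approx(6.14, abs=0.15)

    def test_monte_carlo_unbiased(self):
        rng = np.random.default_rng(42)
        zs = [
            fit_twilight_slope(synth_twilight(SITE, rng=rng), SITE).Z_hat
            for _ in range(500)
        ]
        se = np.std(zs) / np.sqrt(len(zs))
        assert np.mean(zs) == pytest.approx(0.23, abs=3 * se + 1e-3)

    def test_too_few_samples(self):
        tw = synth_twilight(SITE)
        short = TwilightData(0, "rise", tw.anchor_time, tw.times[:2], tw.log_light[:2])
        with pytest.raises(FitError):
            fit_twilight_slope(short, SITE)

    def test_flat_design_rejected(self):
        # all samples at one instant: zero template variation at any site
        t = np.full(5, np.datetime64("2011-01-15T06:30:00"))
        tw = TwilightData(0, "rise", t[0], t, np.log([3, 5, 9, 17, 30]))
        with pytest.raises(FitError):
            fit_twilight_slope(tw, SITE)

    def test_interval_mle_matches_bruteforce_optimum(self):
        # the scoring iteration must land on the interval-likelihood optimum
        from scipy.optimize import minimize
        from scipy.special import ndtr

        from luxtrack.calibration import sample_intervals
        from luxtrack.solar import solar_elevation
        from luxtrack.template import log_surface_light

        tw = synth_twilight(SITE, rng=np.random.default_rng(5))
        b = log_surface_light(solar_elevation(SITE, tw.times))
        lo, hi = sample_intervals(tw.log_light)

        def nll(p):
            a, z, s = p
            s = abs(s) + 1e-6
            mu = a + z * b
            be = np.where(np.isinf(hi), np.inf, (hi - mu) / s)
            P = ndtr(be) - ndtr((lo - mu) / s)
            return -np.sum(np.log(np.clip(P, 1e-300, None)))

        res = minimize(nll, [6.0, 0.22, 0.3], method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 6000})
        slope, _, _, _ = interval_mle_fit(b[None, :], tw.log_light, n_iter=25)
        assert slope[0] == pytest.approx(res.x[1], abs=2e-3)


class TestIntervalMoments:
    @pytest.mark.parametrize(
        "mu,sigma,lo,hi",
        [(0.0, 1.0, -0.5, 0.7), (2.0, 0.3, 2.5, np.inf), (1.0, 0.5, -np.inf, 0.2)],
    )
    def test_against_numerical_integration(self, mu, sigma, lo, hi):
        from luxtrack.calibration import interval_moments

        mean, var = interval_moments(np.array(mu), sigma, lo, hi)
        a = lo if np.isfinite(lo) else mu - 12 * sigma
        b = hi if np.isfinite(hi) else mu + 12 * sigma
        y = np.linspace(a, b, 200_001)
        pdf = np.exp(-0.5 * ((y - mu) / sigma) ** 2)
        Z = np.trapezoid(pdf, y)
        m_num = np.trapezoid(y * pdf, y) / Z
        v_num = np.trapezoid((y - m_num) ** 2 * pdf, y) / Z
        assert float(mean) == pytest.approx(m_num, abs=1e-6)
        assert float(var) == pytest.approx(v_num, rel=1e-5)


class TestCalibrate:
    def _fits(self, n, z=0.23, rng=None):
        rng = rng or np.random.default_rng(0)
        return [
            TwilightFit(Z_hat=z * np.exp(rng.normal(0, 0.04)), sigma_Z=0.01,
                        a_hat=6.0, resid_sd=0.32, n_samples=10)
            for _ in range(n)
        ]

    def test_requires_ten_fits(self):
        with pytest.raises(CalibrationError):
            calibrate(self._fits(9))

    def test_negative_slopes_dropped(self):
        fits = self._fits(20)
        fits[3] = TwilightFit(Z_hat=-0.1, sigma_Z=0.01, a_hat=6.0, resid_sd=0.3, n_samples=10)
        params = calibrate(fits)
        assert params.sigma_err == pytest.approx(0.32, abs=0.02)
        # 19 usable fits is still enough; dropping below 10 is not
        with pytest.raises(CalibrationError):
            calibrate(fits[:10])  # 9 positive + 1 negative

    def test_identical_slopes_floored(self):
        fits = [TwilightFit(0.23, 0.01, 6.0, 0.32, 10) for _ in range(12)]
        assert calibrate(fits).sdlog_Z == pytest.approx(1e-3)

    def test_drop_rule_applied(self):
        fits = self._fits(30)
        params = calibrate(fits, drop_rule=lambda f: f.n_samples < 5)
        assert params.meanlog_Z == pytest.approx(np.log(0.23), abs=0.05)


class TestParameterization:
    def test_natural_scale_mapping(self):
        p = CalibrationParams.from_natural(0.23, 0.01, 0.32)
        assert p.meanlog_Z == pytest.approx(np.log(0.23))
        assert p.sdlog_Z == pytest.approx(0.01 / 0.23)
        assert p.natural_center == pytest.approx(0.23)
        assert p.parameterization == "natural-scale"

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            CalibrationParams(meanlog_Z=0.0, sdlog_Z=0.0, sigma_err=0.3)
        with pytest.raises(ValueError):
            CalibrationParams.from_natural(-0.2, 0.01, 0.3)


class TestAgeing:
    def setup_method(self):
        self.p = CalibrationParams(
            meanlog_Z=np.log(0.23),
            sdlog_Z=0.05,
            sigma_err=0.32,
            ageing=(np.log(0.25), np.log(0.20), "2011-01-01", "2011-12-31"),
        )

    def test_endpoints_and_midpoint(self):
        assert ageing_slope(self.p, "2011-01-01") == pytest.approx(np.log(0.25))
        assert ageing_slope(self.p, "2011-12-31") == pytest.approx(np.log(0.20))
        mid = ageing_slope(self.p, "2011-07-02")
        assert mid == pytest.approx((np.log(0.25) + np.log(0.20)) / 2, abs=1e-3)

    def test_constant_when_start_equals_end(self):
        p = CalibrationParams(np.log(0.23), 0.05, 0.32,
                              ageing=(np.log(0.25), np.log(0.25), "2011-01-01", "2011-12-31"))
        assert ageing_slope(p, "2011-06-01") == pytest.approx(np.log(0.25))

    def test_outside_deployment_clamped_with_warning(self):
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            v = ageing_slope(self.p, "2012-06-01")
        assert v == pytest.approx(np.log(0.20))
        assert any("clamp" in str(x.message) for x in w)

    def test_no_ageing_passthrough(self):
        p = CalibrationParams(np.log(0.23), 0.05, 0.32)
        assert ageing_slope(p, "2015-01-01") == p.meanlog_Z
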