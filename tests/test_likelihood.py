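import numpy as np
import pytest

from luxtrack import (
    CalibrationParams,
    GeoPosition,
    TwilightData,
    make_grid,
    prefilter_outliers,
    twilight_likelihood,
)
from luxtrack.likelihood import _overlap_integral, surfaces_to_table

from conftest import synth_twilight


@pytest.fixture(scope="module")
def params():
    return CalibrationParams.from_natural(0.23, 0.01, 0.32)


@pytest.fixture(scope="module")
def grid():
    return make_grid(GeoPosition(0, 40), 400.0, 50.0)


def anchor_only(i, kind, t):
    return TwilightData(i, kind, np.datetime64(t, "s"))


class TestOverlapIntegral:
    def test_against_dense_trapezoid(self):
        rng = np.random.default_rng(0)
        meanlog, sdlog = np.log(0.23), 0.05
        for _ in range(5):
            z_hat = rng.uniform(0.15, 0.3)
            se = rng.uniform(0.005, 0.05)
            ours = _overlap_integral(meanlog, sdlog, z_hat, se)[0]
            z = np.linspace(1e-9, 1.2, 1_000_000)
            prior = np.exp(-0.5 * ((np.log(z) - meanlog) / sdlog) ** 2) / (
                z * sdlog * np.sqrt(2 * np.pi)
            )
            lik = np.exp(-0.5 * ((z - z_hat) / se) ** 2) / (se * np.sqrt(2 * np.pi))
            dense = np.trapezoid(prior * lik, z)
            assert ours == pytest.approx(dense, rel=1e-6)

    def test_negative_slope_estimate_gives_tiny_mass(self):
        lo = _overlap_integral(np.log(0.23), 0.05, -0.2, 0.01)[0]
        hi = _overlap_integral(np.log(0.23), 0.05, 0.23, 0.01)[0]
        assert lo < 1e-6 * hi


class TestTwilightLikelihood:
    def test_peak_at_true_site(self, params, grid):
        tw = synth_twilight(GeoPosition(0, 40), date="2011-01-15", rng=np.random.default_rng(1))
        s = twilight_likelihood(tw, grid, params)
        k = int(np.argmax(s.weights))
        from luxtrack import gc_distance

        d = gc_distance((grid.lon[k], grid.lat[k]), (0.0, 40.0))
        # a single twilight localizes along a broad ridge; the mode must sit
        # on the ridge near the true site rather than at a random node, and
        # the mass centroid must land close to the truth
        assert d < 400.0
        assert s.weights[k] > 2.0 / grid.n_nodes  # sharper than uniform
        cen = (s.weights @ grid.lon, s.weights @ grid.lat)
        assert gc_distance(cen, (0.0, 40.0)) < 150.0

    def test_normalized_and_floored(self, params, grid):
        tw = synth_twilight(GeoPosition(0, 40), rng=np.random.default_rng(2))
        s = twilight_likelihood(tw, grid, params)
        assert s.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert s.weights.min() > 0

    def test_attenuation_causes_no_systematic_displacement(self, params, grid):
        # shading/attenuation only moves the per-twilight intercept, which
        # the fit profiles out; darkening the whole twilight must not shift
        # surfaces systematically (readings requantize, so the invariance is
        # statistical, not sample-exact)
        dlon, dlat = [], []
        for seed in range(12):
            a = synth_twilight(GeoPosition(0, 40), rng=np.random.default_rng(seed))
            b = synth_twilight(
                GeoPosition(0, 40), intercept=6.84, rng=np.random.default_rng(seed)
            )
            wa = twilight_likelihood(a, grid, params).weights
            wb = twilight_likelihood(b, grid, params).weights
            dlon.append(wb @ grid.lon - wa @ grid.lon)
            dlat.append(wb @ grid.lat - wa @ grid.lat)
        assert abs(np.mean(dlat)) < 0.15
        assert abs(np.mean(dlon)) < 0.9

    def test_excluded_twilight_rejected(self, params, grid):
        tw = TwilightData(0, "rise", np.datetime64("2011-01-01T06:00:00"), excluded=True, reason="empty")
        with pytest.raises(ValueError):
            twilight_likelihood(tw, grid, params)

    def test_more_samples_concentrate_the_surface(self, params, grid):
        # entropy with the full sample set <= entropy after thinning to a
        # third of the samples, on average
        rng = np.random.default_rng(4)
        gains = []
        for _ in range(25):
            tw = synth_twilight(GeoPosition(0, 40), rng=rng)
            full = twilight_likelihood(tw, grid, params).weights
            thin = TwilightData(0, tw.kind, tw.anchor_time, tw.times[::3], tw.log_light[::3])
            coarse = twilight_likelihood(thin, grid, params).weights
            H = lambda w: -(w * np.log(w)).sum()
            gains.append(H(coarse) - H(full))
        assert np.mean(gains) > 0

    def test_export_table(self, params, grid):
        tw = synth_twilight(GeoPosition(0, 40), rng=np.random.default_rng(5))
        s = twilight_likelihood(tw, grid, params)
        table = surfaces_to_table([s])
        assert set(table.columns) == {"twilight_index", "node_index", "weight"}
        assert table["weight"].sum() == pytest.approx(1.0, abs=1e-9)


class TestPrefilter:
    def _daily(self, n, shift_min=None, shift_at=None, jitter_min=3.0, seed=9):
        # realistic anchors: constant clock time plus a few minutes of
        # shading jitter (noise-free anchors would make any robust scale
        # estimate collapse to its floor)
        rng = np.random.default_rng(seed)
        tws = []
        for d in range(n):
            j1, j2 = rng.normal(0, jitter_min, 2)
            t = np.datetime64("2011-01-01T05:50:00") + np.timedelta64(d, "D") + np.timedelta64(int(j1 * 60), "s")
            if shift_at is not None and d == shift_at:
                t = t + np.timedelta64(shift_min, "m")
            tws.append(anchor_only(2 * d, "rise", t))
            tws.append(
                anchor_only(
                    2 * d + 1,
                    "set",
                    np.datetime64("2011-01-01T18:05:00") + np.timedelta64(d, "D") + np.timedelta64(int(j2 * 60), "s"),
                )
            )
        return tws

    def test_requires_twenty(self):
        with pytest.raises(ValueError):
            prefilter_outliers(self._daily(5))

    def test_shifted_anchor_flagged(self):
        tws = self._daily(30, shift_min=40, shift_at=15)
        flags = prefilter_outliers(tws)
        assert flags[30]  # the shifted rise
        assert flags.sum() == 1

    def test_single_spike_in_constant_series(self):
        tws = self._daily(25, shift_min=60, shift_at=12)
        flags = prefilter_outliers(tws)
        flagged = np.flatnonzero(flags)
        assert list(flagged) == [24]

    def test_clean_tag_false_positive_rate(self):
        # crossing-longitude screening on clean simulated tags should flag
        # fewer than 2% of twilights
        from luxtrack import SimSpec, detect_twilights, simulate_tag

        total = flagged = 0
        for seed in range(40):
            spec = SimSpec(
                schedule=[(GeoPosition(0, 5), "2011-01-01", "2011-05-01")],
                interval_s=300,
                seed=1000 + seed,
            )
            series, _ = simulate_tag(spec)
            tws = [
                anchor_only(i, kind, t)
                for i, (t, kind) in enumerate(detect_twilights(series, level=32.0))
            ]
            f = prefilter_outliers(tws)
            total += len(f)
            flagged += int(f.sum())
        assert flagged / total < 0.02
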