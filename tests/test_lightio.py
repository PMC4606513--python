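from datetime import timedelta

import numpy as np
import pytest

from luxtrack import (
    GeoPosition,
    LightSeries,
    SimSpec,
    assemble_twilight,
    detect_twilights,
    extract_twilights,
    invert_expected_log_light,
    read_annotations,
    read_light_series,
    simulate_tag,
    solar_elevation,
    write_annotations,
    write_light_series,
)
from luxtrack.lightio import DARK_LOG


def make_series(lights, start="2011-01-01T00:00:00", step_s=120):
    t0 = np.datetime64(start)
    times = t0 + np.arange(len(lights)) * np.timedelta64(step_s, "s")
    return LightSeries(times, np.asarray(lights))


class TestLightSeriesIO:
    def test_csv_round_trip(self, tmp_path):
        p = tmp_path / "light.csv"
        p.write_text("datetime,light\n2011-01-01T00:00:00,0\n2011-01-01T00:02:00,30\n2011-01-01T00:04:00,64\n")
        s = read_light_series(p, "csv")
        assert len(s) == 3 and s.interval_s == 120
        assert list(s.light) == [0, 30, 64]
        q = tmp_path / "copy.csv"
        write_light_series(q, s)
        s2 = read_light_series(q, "csv")
        assert np.array_equal(s.times, s2.times) and np.array_equal(s.light, s2.light)

    def test_bas_lig_round_trip_and_suspect_rows(self, tmp_path):
        p = tmp_path / "tag.lig"
        p.write_text(
            "ok,01/06/11 00:00:00,360201600,12\n"
            "suspect,01/06/11 00:02:00,360201720,99\n"
            "ok,01/06/11 00:04:00,360201840,20\n"
        )
        s = read_light_series(p, "bas_lig")
        assert list(s.light) == [12, 20]  # flagged row dropped (even out-of-range)
        q = tmp_path / "out.lig"
        write_light_series(q, s, "bas_lig")
        assert np.array_equal(read_light_series(q, "bas_lig").light, s.light)

    def test_out_of_range_light_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 64\]"):
            make_series([0, 70, 64])

    def test_non_monotone_time_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("datetime,light\n2011-01-01T00:02:00,0\n2011-01-01T00:00:00,30\n")
        with pytest.raises(ValueError, match="increasing"):
            read_light_series(p, "csv")

    def test_bad_timestamp_reports_row(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("datetime,light\n2011-01-01T00:00:00,0\nnot-a-time,30\n")
        with pytest.raises(ValueError, match="row 2"):
            read_light_series(p, "csv")


class TestDetect:
    def test_noise_free_stationary_two_events_per_day(self):
        params_free = dict(intercept_sd=1e-9, seed=3)
        from luxtrack import CalibrationParams

        calib = CalibrationParams(meanlog_Z=np.log(0.23), sdlog_Z=1e-3, sigma_err=1e-6)
        spec = SimSpec(
            schedule=[(GeoPosition(0, 5), "2011-02-01", "2011-03-01")],
            interval_s=120,
            calib=calib,
            intercept_sd=1e-9,
            seed=3,
        )
        series, _ = simulate_tag(spec)
        ev = detect_twilights(series, level=32.0)
        assert len(ev) == 2 * 28
        kinds = [k for _, k in ev]
        assert all(k != kk for k, kk in zip(kinds, kinds[1:]))  # alternate

    def test_noon_dip_merged_away(self):
        # daylight with a 10-min dark dip at noon: dip crossings cancel
        lights = [0] * 100 + [64] * 150 + [0] * 5 + [64] * 145 + [0] * 100
        s = make_series(lights)
        ev = detect_twilights(s, level=32.0, min_gap=timedelta(hours=4))
        assert len(ev) == 2
        assert [k for _, k in ev] == ["rise", "set"]

    def test_flat_series_no_events(self):
        assert detect_twilights(make_series([0] * 50), level=32.0) == []
        assert detect_twilights(make_series([64] * 50), level=32.0) == []

    def test_anchor_interpolation(self):
        s = make_series([0, 0, 16, 48, 64, 64])
        (t, kind), = detect_twilights(s, level=32.0)
        assert kind == "rise"
        # level 32 sits halfway between records 2 (16) and 3 (48)
        expect = s.times[2] + np.timedelta64(60, "s")
        assert abs((t - expect) / np.timedelta64(1, "s")) <= 1

    def test_level_must_be_interior(self):
        with pytest.raises(ValueError):
            detect_twilights(make_series([0, 64]), level=0.0)

    def test_anchors_match_solar_crossing_times(self):
        # noise-free tag at the equator: anchors should sit within one
        # logging interval of the instant the expected reading crosses the
        # detection level (template inversion + elevation scan oracle)
        from luxtrack import CalibrationParams

        calib = CalibrationParams(meanlog_Z=np.log(0.23), sdlog_Z=1e-3, sigma_err=1e-6)
        spec = SimSpec(
            schedule=[(GeoPosition(0, 0), "2011-03-01", "2011-03-08")],
            interval_s=120,
            calib=calib,
            intercept_sd=1e-9,
            seed=1,
        )
        series, _ = simulate_tag(spec)
        events = detect_twilights(series, level=32.0)
        theta_star = invert_expected_log_light(np.log(32.0), 0.23, 6.14)
        for anchor, kind in events[:6]:
            ts = np.datetime64(anchor) + np.arange(-1800, 1801, 10).astype("timedelta64[s]")
            el = solar_elevation((0.0, 0.0), ts)
            k = int(np.argmin(np.abs(el - theta_star)))
            assert abs((ts[k] - np.datetime64(anchor)) / np.timedelta64(1, "s")) <= 150


class TestAssemble:
    def test_window_classification(self):
        s = make_series([0, 4, 18, 55, 64])
        tw = assemble_twilight(s, (s.times[2], "rise"), window=timedelta(minutes=75))
        assert tw.n_samples == 5
        vals = np.exp(tw.log_light)
        # interior samples carry exact log device units
        assert list(np.round(vals[1:4]).astype(int)) == [4, 18, 55]
        # dark zero held at its censoring sentinel, saturation at the clip value
        assert tw.log_light[0] == pytest.approx(DARK_LOG)
        assert tw.log_light[-1] == pytest.approx(np.log(64))

    def test_all_dark_window_excluded(self):
        s = make_series([0] * 10)
        tw = assemble_twilight(s, (s.times[5], "rise"))
        assert tw.excluded and tw.reason == "empty"

    def test_sample_count_bounded_by_window(self):
        spec = SimSpec(schedule=[(GeoPosition(0, 5), "2011-01-01", "2011-01-15")], interval_s=120, seed=0)
        series, _ = simulate_tag(spec)
        for tw in extract_twilights(series, level=32.0):
            assert 1 <= tw.n_samples <= 2 * 240 * 60 / 120 + 2

    def test_ten_minute_interval_few_shape_samples(self):
        # the classic clipped-tag regime: only a handful of informative
        # (non-clipped) readings per twilight at 10-min logging
        spec = SimSpec(schedule=[(GeoPosition(0, 5), "2011-01-01", "2011-02-01")], interval_s=600, seed=4)
        series, _ = simulate_tag(spec)
        counts = []
        for tw in extract_twilights(series, level=32.0):
            if tw.excluded:
                continue
            interior = (tw.log_light > DARK_LOG + 1e-9) & (tw.log_light < np.log(63.5))
            counts.append(int(interior.sum()))
        assert 3 <= np.median(counts) <= 9


class TestAnnotations:
    def test_round_trip(self, tmp_path):
        s = make_series([0, 10, 40, 64, 64, 40, 10, 0], step_s=7200)
        tws = extract_twilights(s, level=32.0, min_gap=timedelta(hours=2))
        p = tmp_path / "ann.csv"
        write_annotations(p, tws, level=32.0)
        back = read_annotations(p)
        assert len(back) == len(tws)
        for a, b in zip(tws, back):
            assert a.kind == b.kind and not b.excluded
            assert abs((np.datetime64(a.anchor_time, "s") - b.anchor_time) / np.timedelta64(1, "s")) <= 1

    def test_excluded_flag_round_trip(self, tmp_path):
        from luxtrack import TwilightData

        tw = TwilightData(0, "set", np.datetime64("2011-01-01T18:00:00"), excluded=True, reason="manual")
        p = tmp_path / "ann.csv"
        write_annotations(p, [tw])
        assert read_annotations(p)[0].excluded

    def test_unknown_kind_token_rejected(self, tmp_path):
        p = tmp_path / "ann.csv"
        p.write_text("datetime,light,twilight,excluded\n2011-01-01T06:00:00,,dusk2,False\n")
        with pytest.raises(ValueError, match="dusk2"):
            read_annotations(p)

    def test_export_count_matches_detection(self, tmp_path):
        spec = SimSpec(schedule=[(GeoPosition(0, 20), "2011-04-01", "2011-04-20")], interval_s=300, seed=2)
        series, _ = simulate_tag(spec)
        tws = extract_twilights(series, level=32.0)
        p = tmp_path / "tags.csv"
        write_annotations(p, tws, level=32.0)
        assert len(read_annotations(p)) == len(detect_twilights(series, level=32.0))
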