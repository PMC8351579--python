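"""Readers, writers, and 5-minute binning of detection events."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from surveypower import data_model as dm


def _csv(text: str) -> io.StringIO:
    return io.StringIO(text.strip() + "\n")


class TestReadDetectionEvents:
    def test_direct_parse(self):
        events = dm.read_detection_events(
            _csv("site_id,start_iso8601,duration_s\nP1,2016-02-20T21:03:17,12.4")
        )
        assert len(events) == 1
        assert events.loc[0, "site_id"] == "P1"
        assert events.loc[0, "start"] == pd.Timestamp("2016-02-20 21:03:17")
        assert events.loc[0, "duration_s"] == pytest.approx(12.4)

    def test_empty_file_with_header(self):
        events = dm.read_detection_events(_csv("site_id,start_iso8601,duration_s"))
        assert len(events) == 0

    def test_negative_duration_rejected_with_line(self):
        with pytest.raises(dm.FormatError, match="line 3"):
            dm.read_detection_events(
                _csv(
                    "site_id,start_iso8601,duration_s\n"
                    "P1,2016-02-20T21:03:17,5.0\n"
                    "P1,2016-02-20T21:04:00,-1"
                )
            )

    def test_missing_column_named(self):
        with pytest.raises(dm.FormatError, match="duration_s"):
            dm.read_detection_events(_csv("site_id,start_iso8601\nP1,2016-02-20T21:03:17"))

    def test_unparseable_timestamp_names_line(self):
        with pytest.raises(dm.FormatError, match="line 2"):
            dm.read_detection_events(
                _csv("site_id,start_iso8601,duration_s\nP1,not-a-time,5.0")
            )


def _events(*rows):
    return pd.DataFrame(
        [{"site_id": s, "start": pd.Timestamp(t), "duration_s": d} for s, t, d in rows],
        columns=["site_id", "start", "duration_s"],
    )


class TestBinning:
    @pytest.fixture()
    def evening_coverage(self):
        # one site, one date, bins 21:00-21:55
        return dm.full_coverage(["P1"], ["2016-02-20"], bin_starts=range(21 * 60, 22 * 60, 5))

    def test_short_event_ignored(self, evening_coverage):
        table = dm.bin_events_to_intervals(
            _events(("P1", "2016-02-20 21:02:00", 2.9)), evening_coverage
        )
        assert table["detected"].sum() == 0

    def test_exactly_threshold_event_excluded(self, evening_coverage):
        table = dm.bin_events_to_intervals(
            _events(("P1", "2016-02-20 21:02:00", 3.0)), evening_coverage
        )
        assert table["detected"].sum() == 0

    def test_event_spanning_two_bins_marks_both(self, evening_coverage):
        table = dm.bin_events_to_intervals(
            _events(("P1", "2016-02-20 21:04:58", 10.0)), evening_coverage
        )
        marked = set(table.loc[table["detected"] == 1, "bin_start"])
        assert marked == {21 * 60, 21 * 60 + 5}

    def test_no_events_gives_all_zero_rows(self, evening_coverage):
        table = dm.bin_events_to_intervals(_events(), evening_coverage)
        assert len(table) == 12
        assert table["detected"].sum() == 0

    def test_event_outside_coverage_warns_and_dropped(self, evening_coverage):
        with pytest.warns(UserWarning, match="1 event"):
            table = dm.bin_events_to_intervals(
                _events(("P2", "2016-02-20 21:02:00", 10.0)), evening_coverage
            )
        assert table["detected"].sum() == 0

    def test_event_crossing_midnight_lands_on_both_dates(self):
        coverage = dm.full_coverage(["P1"], ["2016-02-20", "2016-02-21"])
        table = dm.bin_events_to_intervals(
            _events(("P1", "2016-02-20 23:59:00", 120.0)), coverage
        )
        marked = table[table["detected"] == 1]
        assert set(marked["date"].dt.strftime("%Y-%m-%d")) == {"2016-02-20", "2016-02-21"}

    @settings(max_examples=25, deadline=None)
    @given(st.data())
    def test_matches_brute_force_overlap(self, data):
        """Sum of detected equals the bins overlapped by >=3s events (brute force)."""
        n_events = data.draw(st.integers(0, 15))
        rows = []
        for _ in range(n_events):
            minute = data.draw(st.integers(0, 23 * 60))
            second = data.draw(st.integers(0, 59))
            duration = data.draw(st.floats(0.5, 2000, allow_nan=False))
            rows.append(
                ("P1", pd.Timestamp("2016-03-05") + pd.Timedelta(minutes=minute, seconds=second),
                 duration)
            )
        events = _events(*rows)
        coverage = dm.full_coverage(["P1"], ["2016-03-05"])
        table = dm.bin_events_to_intervals(events, coverage)

        day0 = pd.Timestamp("2016-03-05")
        expected = np.zeros(dm.BINS_PER_DAY, dtype=int)
        for _, ev in events.iterrows():
            if ev.duration_s <= 3.0:
                continue
            for b in range(dm.BINS_PER_DAY):
                b0 = day0 + pd.Timedelta(minutes=5 * b)
                b1 = b0 + pd.Timedelta(minutes=5)
                if ev.start < b1 and ev.start + pd.Timedelta(seconds=ev.duration_s) > b0:
                    expected[b] = 1
        got = table.sort_values("bin_start")["detected"].to_numpy()
        assert (got == expected).all()

    def test_binning_idempotent(self, random_pool):
        """Re-binning a table's own positive bins as 300-s events reproduces it."""
        table = random_pool.intervals
        sub = table[table["date"] == table["date"].iloc[0]]
        pos = sub[sub["detected"] == 1]
        events = pd.DataFrame(
            {
                "site_id": pos["site_id"],
                "start": pd.to_datetime(pos["date"]) + pd.to_timedelta(pos["bin_start"], unit="m"),
                "duration_s": 300.0,
            }
        )
        rebinned = dm.bin_events_to_intervals(events, sub[["site_id", "date", "bin_start"]])
        merged = sub.merge(rebinned, on=["site_id", "date", "bin_start"], suffixes=("", "_re"))
        assert (merged["detected"] == merged["detected_re"]).all()


class TestIntervalTableIO:
    def test_round_trip_identity(self, tmp_path):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(
            {
                "site_id": rng.choice(["P1", "P2"], 100),
                "date": pd.to_datetime(rng.choice(pd.date_range("2015-01-01", "2015-07-31"), 100)),
                "bin_start": rng.choice(np.arange(0, 1440, 5), 100),
                "detected": rng.integers(0, 2, 100),
            }
        ).drop_duplicates(["site_id", "date", "bin_start"])
        path = tmp_path / "intervals.csv"
        dm.write_interval_table(table, path)
        back = dm.read_interval_table(path)
        pd.testing.assert_frame_equal(back, table.reset_index(drop=True), check_dtype=False)

    def test_detected_out_of_range_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("site_id,date,bin_start,detected\nP1,2016-02-01,21:00,2\n")
        with pytest.raises(dm.FormatError, match="detected"):
            dm.read_interval_table(path)

    def test_header_only_gives_empty_table(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("site_id,date,bin_start,detected\n")
        assert len(dm.read_interval_table(path)) == 0

    def test_off_grid_bin_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("site_id,date,bin_start,detected\nP1,2016-02-01,21:03,1\n")
        with pytest.raises(dm.FormatError, match="grid"):
            dm.read_interval_table(path)


class TestEnvAndMoonIO:
    def test_env_round_trip(self, tmp_path, default_dataset):
        env = default_dataset["env"][dm.ENV_COLUMNS].head(200)
        path = tmp_path / "env.csv"
        dm.write_hourly_environment(env, path)
        back = dm.read_hourly_environment(path)
        pd.testing.assert_frame_equal(back, env.reset_index(drop=True), check_dtype=False)

    def test_rh_above_100_rejected(self, tmp_path):
        path = tmp_path / "env.csv"
        path.write_text(
            "timestamp_iso8601,temp_c,rh_pct,wind_kmph,pressure,precip_mm\n"
            "2016-02-01T00:00:00,10,101,5,29.5,0\n"
        )
        with pytest.raises(dm.FormatError, match="rh_pct"):
            dm.read_hourly_environment(path)

    def test_duplicate_timestamp_rejected(self, tmp_path):
        path = tmp_path / "env.csv"
        path.write_text(
            "timestamp_iso8601,temp_c,rh_pct,wind_kmph,pressure,precip_mm\n"
            "2016-02-01T00:00:00,10,80,5,29.5,0\n"
            "2016-02-01T00:00:00,11,80,5,29.5,0\n"
        )
        with pytest.raises(dm.FormatError, match="duplicated"):
            dm.read_hourly_environment(path)

    def test_column_map_adapts_foreign_headers(self, tmp_path):
        path = tmp_path / "lcd.csv"
        path.write_text(
            "DATE,HourlyDryBulbTemperature,HourlyRelativeHumidity,HourlyWindSpeed,"
            "HourlyStationPressure,HourlyPrecipitation\n"
            "2016-02-01T00:00:00,10,80,5,29.5,0\n"
        )
        env = dm.read_hourly_environment(
            path,
            column_map={
                "DATE": "timestamp_iso8601",
                "HourlyDryBulbTemperature": "temp_c",
                "HourlyRelativeHumidity": "rh_pct",
                "HourlyWindSpeed": "wind_kmph",
                "HourlyStationPressure": "pressure",
                "HourlyPrecipitation": "precip_mm",
            },
        )
        assert env.loc[0, "temp_c"] == 10

    @pytest.mark.parametrize("raw,expected", [("91", 0.91), ("0.5", 0.5)])
    def test_moon_percent_autodetection(self, tmp_path, raw, expected):
        path = tmp_path / "moon.csv"
        if raw == "0.5":
            path.write_text(f"date,illumination\n2016-02-01,{raw}\n")
        else:
            # a >1 value anywhere flips the whole column to percent
            path.write_text(f"date,illumination\n2016-02-01,{raw}\n2016-02-02,40\n")
        moon = dm.read_moon(path)
        assert moon.loc[0, "illumination"] == pytest.approx(expected)

    def test_moon_duplicate_date_rejected(self, tmp_path):
        path = tmp_path / "moon.csv"
        path.write_text("date,illumination\n2016-02-01,0.5\n2016-02-01,0.6\n")
        with pytest.raises(dm.FormatError, match="duplicated"):
            dm.read_moon(path)
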