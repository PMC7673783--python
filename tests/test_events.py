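"""Detection-event I/O, independence filtering, detection histories, filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dielaccess import events as ev
from dielaccess.density import TWO_PI


class TestReadDetections:
    def test_well_formed_csv(self, tmp_path, small_events):
        p = tmp_path / "events.csv"
        small_events.head(3).to_csv(p, index=False)
        table, report = ev.read_detections(p)
        assert len(table) == 3
        assert report.n_rejected == 0

    def test_missing_species_column_names_it(self, tmp_path):
        p = tmp_path / "bad.csv"
        pd.DataFrame({"site_id": ["a"], "timestamp": ["2017-01-01"]}).to_csv(p, index=False)
        with pytest.raises(ev.FormatError, match="species"):
            ev.read_detections(p)

    def test_single_bad_timestamp_logged_not_fatal(self, tmp_path):
        n = 1000
        df = pd.DataFrame({
            "site_id": "s1",
            "species": "kob",
            "timestamp": ["2017-01-01 12:00:00"] * n,
        })
        df.loc[500, "timestamp"] = "not-a-time"
        p = tmp_path / "events.csv"
        df.to_csv(p, index=False)
        table, report = ev.read_detections(p)
        assert len(table) == n - 1
        assert report.n_rejected == 1

    def test_too_many_bad_rows_aborts(self, tmp_path):
        df = pd.DataFrame({
            "site_id": ["s1"] * 10, "species": ["kob"] * 10,
            "timestamp": ["bad"] * 5 + ["2017-01-01"] * 5,
        })
        p = tmp_path / "events.csv"
        df.to_csv(p, index=False)
        with pytest.raises(ev.FormatError):
            ev.read_detections(p)

    def test_column_map(self, tmp_path):
        df = pd.DataFrame({"station": ["a"], "animal": ["kob"], "dt": ["2017-01-01"]})
        p = tmp_path / "events.csv"
        df.to_csv(p, index=False)
        table, _ = ev.read_detections(
            p, column_map={"station": "site_id", "animal": "species", "dt": "timestamp"})
        assert list(table["species"]) == ["kob"]


class TestIndependenceFilter:
    def test_quiet_period_rule(self, small_events):
        out = ev.filter_independent_events(small_events, 30)
        s1kob = out[(out.site_id == "s1") & (out.species == "kob")]
        # t, t+10min, t+40min -> keep t and t+40 (30 min after the retained one)
        assert list(s1kob["timestamp"].dt.strftime("%H:%M")) == ["06:00", "06:40", "06:00"]

    def test_sites_independent(self, small_events):
        out = ev.filter_independent_events(small_events, 30)
        # s1 and s2 kob events 1 min apart are both retained
        assert (out.site_id == "s2").sum() == 3

    def test_exact_gap_inclusive(self):
        """Events exactly quiet_minutes apart are all retained (>= rule)."""
        ts = pd.date_range("2017-01-01", periods=100, freq="30min")
        df = pd.DataFrame({"site_id": "s", "species": "kob", "timestamp": ts, "year": 2017})
        out = ev.filter_independent_events(df, 30)
        assert len(out) == 100

    def test_compares_to_last_retained_not_last_raw(self):
        # events every 20 min: keep 0, drop 20, keep 40, drop 60... -> half kept
        ts = pd.date_range("2017-01-01", periods=10, freq="20min")
        df = pd.DataFrame({"site_id": "s", "species": "kob", "timestamp": ts, "year": 2017})
        out = ev.filter_independent_events(df, 30)
        assert len(out) == 5

    def test_idempotent(self, small_events):
        once = ev.filter_independent_events(small_events, 30)
        twice = ev.filter_independent_events(once, 30)
        pd.testing.assert_frame_equal(once, twice)

    def test_negative_quiet_rejected(self, small_events):
        with pytest.raises(ValueError):
            ev.filter_independent_events(small_events, -1)

    @given(st.integers(min_value=0, max_value=120), st.integers(min_value=0, max_value=120))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_monotone_in_quiet_minutes(self, q1, q2):
        ts = pd.to_datetime("2017-01-01") + pd.to_timedelta(
            np.random.default_rng(0).integers(0, 600, 40), unit="min")
        df = pd.DataFrame({"site_id": "s", "species": "kob",
                           "timestamp": sorted(ts), "year": 2017})
        lo, hi = sorted([q1, q2])
        n_short = len(ev.filter_independent_events(df, lo))
        n_long = len(ev.filter_independent_events(df, hi))
        assert n_long <= n_short <= len(df)


class TestClockToRadians:
    @pytest.mark.parametrize("clock,expected", [
        ("2017-01-01 00:00:00", 0.0),
        ("2017-01-01 12:00:00", np.pi),
        ("2017-01-01 18:00:00", 3 * np.pi / 2),
    ])
    def test_reference_times(self, clock, expected):
        assert ev.clock_to_radians(pd.Timestamp(clock)) == pytest.approx(expected)

    def test_periodic_in_days(self):
        a = ev.clock_to_radians(pd.Timestamp("2017-01-01 07:30:00"))
        b = ev.clock_to_radians(pd.Timestamp("2017-01-02 07:30:00"))
        assert a == pytest.approx(b)


class TestDetectionHistory:
    def _deployments(self):
        return pd.DataFrame({
            "site_id": ["c1", "c2"], "year": [2017, 2017],
            "start_date": ["2017-01-01", "2017-01-01"],
            "end_date": ["2017-05-21", "2017-05-21"],  # 140 days -> 10 occasions
            "SAV": [0.9, 0.8],
        })

    def test_single_event_marks_one_occasion(self):
        events = pd.DataFrame({
            "site_id": ["c1"], "species": ["human"],
            "timestamp": [pd.Timestamp("2017-01-20 10:00:00")],  # day 19 -> occasion 2
            "year": [2017],
        })
        h = ev.build_detection_history(events, self._deployments(), "human")
        assert h.y.shape == (2, 10)
        assert h.y[0].tolist() == [0, 1, 0, 0, 0, 0, 0, 0, 0, 0]
        assert np.nansum(h.y[1]) == 0

    def test_occasion_count_from_duration(self):
        dep = self._deployments()
        dep["end_date"] = "2017-03-12"  # 70 days -> 5 occasions
        h = ev.build_detection_history(pd.DataFrame(
            {"site_id": [], "species": [], "timestamp": [], "year": []}), dep, "human")
        assert h.n_occasions == 5

    def test_partial_occasion_rule(self):
        dep = self._deployments()
        dep["end_date"] = "2017-03-20"  # 78 days = 5 occasions + 8 days -> kept
        h = ev.build_detection_history(pd.DataFrame(
            {"site_id": [], "species": [], "timestamp": [], "year": []}), dep, "human")
        assert h.n_occasions == 6
        dep["end_date"] = "2017-03-17"  # 75 days = 5 occasions + 5 days -> dropped
        h = ev.build_detection_history(pd.DataFrame(
            {"site_id": [], "species": [], "timestamp": [], "year": []}), dep, "human")
        assert h.n_occasions == 5

    def test_orphan_event_rejected(self):
        events = pd.DataFrame({
            "site_id": ["c9"], "species": ["human"],
            "timestamp": [pd.Timestamp("2017-01-02")], "year": [2017],
        })
        with pytest.raises(ev.FormatError):
            ev.build_detection_history(events, self._deployments(), "human")

    def test_site_is_cell_by_year(self):
        dep = pd.concat([self._deployments(), self._deployments().assign(year=2018,
                        start_date="2018-01-01", end_date="2018-05-21")])
        h = ev.build_detection_history(pd.DataFrame(
            {"site_id": [], "species": [], "timestamp": [], "year": []}), dep, "human")
        assert h.n_sites == 4
        assert sorted(set(h.cell_key)) == ["c1", "c2"]


class TestSpeciesFilters:
    def _events(self, counts: dict):
        rows = []
        for sp, n in counts.items():
            for i in range(n):
                rows.append(("s1", sp, pd.Timestamp("2017-01-01") + pd.Timedelta(hours=i)))
        df = pd.DataFrame(rows, columns=["site_id", "species", "timestamp"])
        df["year"] = 2017
        return df

    def test_threshold_is_strictly_less_than(self):
        out, report = ev.apply_species_filters(self._events({"a": 49, "b": 50}), 50)
        assert set(out["species"]) == {"b"}
        assert "below_min_detections:49" == report["a"]

    def test_merge_before_count_threshold(self):
        # 30 + 30 detections merge to 60 >= 50, so the merged taxon survives
        out, _ = ev.apply_species_filters(
            self._events({"red_flanked_duiker": 30, "common_duiker": 30}),
            50, merges={"red_flanked_duiker": "duiker", "common_duiker": "duiker"})
        assert set(out["species"]) == {"duiker"}
        assert len(out) == 60

    def test_exclusions(self):
        out, report = ev.apply_species_filters(
            self._events({"elephant": 100, "kob": 100}), 50, exclusions=("elephant",))
        assert set(out["species"]) == {"kob"}
        assert report["elephant"] == "excluded"

    def test_identity_with_no_rules(self):
        events = self._events({"a": 60, "b": 70})
        out, report = ev.apply_species_filters(events, 50)
        assert set(out["species"]) == {"a", "b"}
        assert report == {}


class TestPoolGuild:
    def test_single_member_identity(self, small_events):
        pooled = ev.pool_guild(small_events, ["kob"])
        single = ev.species_sample(small_events, "kob")
        assert np.allclose(np.sort(pooled.times), np.sort(single.times))

    def test_counts_add(self, small_events):
        pooled = ev.pool_guild(small_events, ["kob", "warthog"])
        assert pooled.n == len(small_events)

    def test_antipodal_species_cancel(self):
        """Equal-n concentrated samples 12 h apart pool to resultant ~0."""
        rng = np.random.default_rng(3)
        t1 = rng.vonmises(0.0, 50.0, 500) % TWO_PI
        t2 = rng.vonmises(np.pi, 50.0, 500) % TWO_PI
        ts = pd.to_datetime("2017-01-01") + pd.to_timedelta(
            np.concatenate([t1, t2]) / TWO_PI * 24 * 3600, unit="s")
        df = pd.DataFrame({"site_id": "s", "species": ["a"] * 500 + ["b"] * 500,
                           "timestamp": ts, "year": 2017})
        pooled = ev.pool_guild(df, ["a", "b"])
        r = np.hypot(np.cos(pooled.times).mean(), np.sin(pooled.times).mean())
        assert r < 0.05

    def test_empty_pool_is_error(self, small_events):
        with pytest.raises(ValueError):
            ev.pool_guild(small_events, ["lion"])
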