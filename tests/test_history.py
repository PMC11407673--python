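"""Detection-history builder: independence filtering, site-year stacking,
occasion binning against hand-computed matrices, and effort bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import camtrap_occupancy as co
from camtrap_occupancy.history import OverlapError, summarize_effort


def _records(rows):
    return pd.DataFrame(rows, columns=["station_id", "timestamp"])


class TestIndependenceFilter:
    def test_hand_example_30_minutes(self):
        rec = _records(
            [
                ("A", "2021-01-01 10:00"),
                ("A", "2021-01-01 10:10"),
                ("A", "2021-01-01 10:40"),
            ]
        )
        out = co.filter_independent_records(rec, 30)
        assert list(out["timestamp"].dt.strftime("%H:%M")) == ["10:00", "10:40"]

    def test_zero_interval_is_identity(self):
        rec = _records(
            [("A", "2021-01-01 10:00"), ("A", "2021-01-01 10:00:30"), ("A", "2021-01-01 10:01")]
        )
        assert len(co.filter_independent_records(rec, 0)) == 3

    def test_independence_is_per_station(self):
        rec = _records([("A", "2021-01-01 10:00"), ("B", "2021-01-01 10:00")])
        assert len(co.filter_independent_records(rec, 60)) == 2

    def test_negative_interval_rejected(self):
        with pytest.raises(ValueError):
            co.filter_independent_records(_records([("A", "2021-01-01")]), -1)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        minutes=st.lists(st.integers(0, 600), min_size=1, max_size=25),
        interval=st.integers(1, 120),
    )
    def test_retained_events_are_spaced_at_least_interval(self, minutes, interval):
        base = pd.Timestamp("2021-06-01")
        rec = _records(
            [("A", base + pd.Timedelta(minutes=m)) for m in minutes]
        )
        out = co.filter_independent_records(rec, interval)
        ts = out["timestamp"].sort_values().to_numpy()
        if len(ts) > 1:
            gaps = np.diff(ts) / np.timedelta64(1, "m")
            assert (gaps >= interval).all()


class TestStacking:
    def test_year_boundary_split(self):
        dep = pd.DataFrame(
            [{"station_id": "A", "start": "2020-12-01", "end": "2021-01-31", "survey": "OC"}]
        )
        out = co.stack_site_years(dep)
        assert len(out) == 2
        assert out.loc[0, "year"] == 2020
        assert str(out.loc[0, "end"].date()) == "2020-12-31"
        assert out.loc[1, "year"] == 2021
        assert str(out.loc[1, "start"].date()) == "2021-01-01"
        assert str(out.loc[1, "end"].date()) == "2021-01-31"

    def test_within_year_unchanged_and_empty_ok(self):
        dep = pd.DataFrame(
            [{"station_id": "A", "start": "2021-03-01", "end": "2021-05-30", "survey": "OC"}]
        )
        out = co.stack_site_years(dep)
        assert len(out) == 1 and out.loc[0, "year"] == 2021
        empty = co.stack_site_years(dep.iloc[0:0])
        assert len(empty) == 0 and "year" in empty.columns

    def test_overlap_within_station_year_is_error(self):
        dep = pd.DataFrame(
            [
                {"station_id": "A", "start": "2021-03-01", "end": "2021-05-30", "survey": "OC"},
                {"station_id": "A", "start": "2021-05-01", "end": "2021-06-15", "survey": "OC"},
            ]
        )
        with pytest.raises(OverlapError):
            co.stack_site_years(dep)


class TestBuilder:
    def _dep(self, start, end):
        return co.stack_site_years(
            pd.DataFrame([{"station_id": "A", "start": start, "end": end, "survey": "OC"}])
        )

    def test_45_day_deployment_golden_matrix(self):
        dep = self._dep("2021-01-01", "2021-02-14")  # 45 days
        rec = _records([("A", "2021-01-04 08:00"), ("A", "2021-01-21 17:00")])  # days 3, 20
        hist = co.build_detection_history(rec, dep)
        assert hist.K == 8
        np.testing.assert_array_equal(
            hist.y[0], [1, 1, 0, np.nan, np.nan, np.nan, np.nan, np.nan]
        )
        np.testing.assert_array_equal(hist.effort[0], [15, 15, 15, 0, 0, 0, 0, 0])

    def test_long_deployment_truncated_at_120_days(self):
        dep = self._dep("2021-01-01", "2021-07-20")  # 201 days
        hist = co.build_detection_history(_records([]), dep)
        np.testing.assert_array_equal(hist.effort[0], [15] * 8)
        assert np.all(hist.y[0] == 0)

    def test_partial_terminal_occasion_keeps_true_effort(self):
        dep = self._dep("2021-01-01", "2021-02-04")  # 35 days
        hist = co.build_detection_history(_records([]), dep)
        np.testing.assert_array_equal(hist.effort[0], [15, 15, 5, 0, 0, 0, 0, 0])

    def test_no_records_gives_all_zero_active_row(self):
        dep = self._dep("2021-01-01", "2021-04-30")
        hist = co.build_detection_history(_records([]), dep)
        assert np.all(hist.y[0][hist.observed[0]] == 0)
        assert not np.isnan(hist.y[0][hist.observed[0]]).any()

    def test_orphan_record_dropped_with_warning(self):
        dep = self._dep("2021-01-01", "2021-01-31")
        rec = _records([("A", "2021-06-01 12:00"), ("A", "2021-01-05 12:00")])
        with pytest.warns(UserWarning, match="outside every deployment"):
            hist = co.build_detection_history(rec, dep)
        assert np.nansum(hist.y) == 1  # only the in-window record counts


class TestEffortSummary:
    def test_full_site_is_120_trap_nights(self):
        dep = pd.DataFrame(
            [{"station_id": "A", "start": "2021-01-01", "end": "2021-04-30", "survey": "OC"}]
        )
        hist = co.build_detection_history(
            _records([]), co.stack_site_years(dep)
        )
        assert summarize_effort(hist)["total_trap_nights"] == 120.0

    def test_empty_history_is_all_zero(self):
        hist = co.DetectionHistory(site_index=[], y=np.zeros((0, 8)), effort=np.zeros((0, 8)))
        s = summarize_effort(hist)
        assert s["n_sites"] == 0 and s["total_trap_nights"] == 0.0

    def test_trap_nights_equal_simulated_active_days(self):
        cfg = co.SimulationConfig(n_stations=40, years_per_station=2, seed=21)
        cov = co.simulate_covariates(cfg)
        hist, _ = co.simulate_detection_history(cov, cfg)
        s = summarize_effort(hist)
        assert s["total_trap_nights"] == float(hist.effort.sum())
        assert s["total_trap_nights"] <= hist.n_sites * 120
        # missingness pattern and detections are mutually consistent
        assert np.array_equal(np.isnan(hist.y), hist.effort == 0)
        assert np.all(hist.effort[hist.y == 1.0] > 0)
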