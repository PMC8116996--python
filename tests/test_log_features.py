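"""Sessionization, hourly binning, switch counting and derived rates."""

import numpy as np
import pandas as pd
import pytest

from inboxstress import log_features as lf
from conftest import inbox_event, make_events, other_event


def brute_force_attributed_seconds(times_s, cutoff_s):
    """Per-second scan: second s belongs to the latest event at or before s,
    provided that event is less than cutoff seconds old."""
    total = 0
    t = np.asarray(times_s)
    for s in range(int(t.min()), int(t.max()) + cutoff_s):
        prev = t[t <= s]
        if len(prev) and s - prev.max() < cutoff_s:
            total += 1
    return total


class TestSessionize:
    def test_two_events_then_idle(self):
        ev = make_events(
            [inbox_event("2023-03-06 09:00:00"), inbox_event("2023-03-06 09:02:00")]
        )
        iv = lf.sessionize(ev)
        dur = (iv["end"] - iv["start"]) / pd.Timedelta(minutes=1)
        assert list(dur) == [2.0, 5.0]
        assert dur[iv["category"] == "INBOX"].sum() == 7.0

    def test_single_event_gets_idle_cutoff(self):
        iv = lf.sessionize(make_events([inbox_event("2023-03-06 09:00:00")]))
        assert len(iv) == 1
        assert (iv["end"] - iv["start"]).iloc[0] == pd.Timedelta(minutes=5)

    def test_unsorted_input_rejected(self):
        ev = make_events(
            [inbox_event("2023-03-06 09:05:00"), inbox_event("2023-03-06 09:00:00")]
        )
        with pytest.raises(ValueError, match="sorted"):
            lf.sessionize(ev)

    def test_empty_input(self):
        assert lf.sessionize(make_events([])).empty

    def test_random_gaps_match_per_second_oracle(self, rng):
        # 100 events at random whole-second gaps; total attributed time must
        # equal the brute-force per-second attribution
        gaps = rng.integers(1, 600, size=99)
        times = np.concatenate([[0], np.cumsum(gaps)])
        base = pd.Timestamp("2023-03-06 08:00:00")
        ev = make_events([inbox_event(base + pd.Timedelta(seconds=int(s))) for s in times])
        iv = lf.sessionize(ev)
        total = ((iv["end"] - iv["start"]) / pd.Timedelta(seconds=1)).sum()
        assert total == brute_force_attributed_seconds(times, 300)

    def test_monotone_in_idle_cutoff(self, rng):
        times = np.cumsum(rng.integers(1, 900, size=60))
        base = pd.Timestamp("2023-03-06 08:00:00")
        ev = make_events([inbox_event(base + pd.Timedelta(seconds=int(s))) for s in times])
        totals = []
        for cutoff in (1.0, 2.0, 5.0, 10.0, 30.0):
            iv = lf.sessionize(ev, lf.SessionizationConfig(idle_cutoff_min=cutoff))
            totals.append(((iv["end"] - iv["start"]) / pd.Timedelta(minutes=1)).sum())
        assert all(a <= b + 1e-9 for a, b in zip(totals, totals[1:]))


class TestBinHourly:
    def test_straddle_split_at_anchor(self):
        iv = pd.DataFrame(
            {
                "physician_id": ["P0"],
                "start": [pd.Timestamp("2023-03-06 09:25:00")],
                "end": [pd.Timestamp("2023-03-06 09:35:00")],
                "category": ["INBOX"],
                "message_type": ["PATIENT"],
            }
        )
        out = lf.bin_hourly(iv)
        assert len(out) == 2
        assert list(out["minutes"]) == [5.0, 5.0]
        assert out["bin_start"].iloc[0] == pd.Timestamp("2023-03-06 08:30:00")

    def test_no_intervals_no_bins(self):
        assert lf.bin_hourly(pd.DataFrame(columns=["physician_id", "start", "end", "category", "message_type"])).empty

    def test_conservation_random_intervals(self, rng):
        starts = np.sort(rng.uniform(0, 86_000, size=200))
        lengths = rng.uniform(1, 3000, size=200)
        base = pd.Timestamp("2023-03-06")
        iv = pd.DataFrame(
            {
                "physician_id": "P0",
                "start": base + pd.to_timedelta(starts, unit="s"),
                "end": base + pd.to_timedelta(starts + lengths, unit="s"),
                "category": "INBOX",
                "message_type": "PATIENT",
            }
        )
        out = lf.bin_hourly(iv)
        assert out["minutes"].sum() == pytest.approx(lengths.sum() / 60, abs=1e-6)


class TestCountsAndRates:
    def test_window_switch_pattern(self):
        ev = make_events(
            [
                inbox_event("2023-03-06 09:00:00", window="A"),
                inbox_event("2023-03-06 09:01:00", window="A"),
                inbox_event("2023-03-06 09:02:00", window="B"),
                inbox_event("2023-03-06 09:03:00", window="A"),
            ]
        )
        assert lf.count_window_switches(ev)["n_window_switches"].sum() == 2

    def test_identical_windows_no_switches(self):
        ev = make_events([inbox_event(f"2023-03-06 09:{m:02d}:00") for m in range(10)])
        assert lf.count_window_switches(ev)["n_window_switches"].sum() == 0

    def test_random_sequence_matches_adjacent_pair_oracle(self, rng):
        ids = rng.integers(0, 5, size=500).astype(str)
        base = pd.Timestamp("2023-03-06 08:00:00")
        ev = make_events(
            [
                inbox_event(base + pd.Timedelta(seconds=10 * i), window=w)
                for i, w in enumerate(ids)
            ]
        )
        oracle = int((ids[1:] != ids[:-1]).sum())
        assert lf.count_window_switches(ev)["n_window_switches"].sum() == oracle

    def test_switching_rate(self):
        hourly = pd.DataFrame({"n_window_switches": [70, 50], "minutes_ehr": [20.0, 10.0]})
        assert lf.switching_rate(hourly) == 4.0
        assert lf.switching_rate(pd.DataFrame({"n_window_switches": [0], "minutes_ehr": [10.0]})) == 0.0
        assert np.isnan(lf.switching_rate(pd.DataFrame({"n_window_switches": [3], "minutes_ehr": [0.0]})))

    @pytest.mark.parametrize("minutes,n,expect", [(46.0, 100, 0.46), (35.0, 100, 0.35)])
    def test_time_per_message(self, minutes, n, expect):
        hourly = pd.DataFrame({"minutes_inbox": [minutes], "n_tasks": [n]})
        assert lf.time_per_message(hourly, n) == pytest.approx(expect)
        assert lf.time_per_message(hourly) == pytest.approx(expect)

    def test_time_per_message_no_messages_missing(self):
        hourly = pd.DataFrame({"minutes_inbox": [10.0], "n_tasks": [0]})
        assert np.isnan(lf.time_per_message(hourly))


class TestHourlyUsage:
    def test_type_minutes_sum_to_inbox_and_inbox_within_ehr(self, small_cohort):
        hourly = lf.build_hourly_usage(small_cohort.events)
        type_sum = sum(hourly[f"minutes_{t.lower()}"] for t in lf.MESSAGE_TYPES)
        assert np.allclose(type_sum, hourly["minutes_inbox"], atol=1e-6)
        assert (hourly["minutes_inbox"] <= hourly["minutes_ehr"] + 1e-9).all()
        assert (hourly["minutes_ehr"] <= 60 + 1e-9).all()

    def test_hourly_conservation_vs_sessionized_total(self, small_cohort):
        ev = small_cohort.events
        iv = lf.sessionize(ev)
        hourly = lf.build_hourly_usage(ev)
        total_iv = ((iv["end"] - iv["start"]) / pd.Timedelta(minutes=1)).sum()
        assert hourly["minutes_ehr"].sum() == pytest.approx(total_iv, abs=1e-6)

    def test_schema_validation(self):
        bad = make_events([inbox_event("2023-03-06 09:00:00")])
        bad.loc[0, "message_type"] = "NONE"  # NONE only allowed for OTHER_EHR
        with pytest.raises(ValueError, match="NONE"):
            lf.validate_events(bad)

    def test_csv_roundtrip(self, tmp_path):
        ev = make_events(
            [inbox_event("2023-03-06 09:00:00"), other_event("2023-03-06 09:01:00")]
        )
        path = tmp_path / "events.csv"
        lf.write_log_events(ev, path)
        back = lf.read_log_events(path)
        assert back["category"].tolist() == ["INBOX", "OTHER_EHR"]
        assert back["timestamp"].iloc[0] == pd.Timestamp("2023-03-06 09:00:00")
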