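"""Stress-sample aggregation, validity filters, and the daily curve."""

import numpy as np
import pandas as pd
import pytest

from inboxstress import hrv_stress as hs


def sample_frame(specs, day="2023-03-06"):
    """(minute_offset, score, activity) -> stress sample frame."""
    base = pd.Timestamp(day)
    return pd.DataFrame(
        {
            "timestamp": [base + pd.Timedelta(minutes=m) for m, _, _ in specs],
            "physician_id": "P0",
            "score": [s for _, s, _ in specs],
            "activity_flag": [a for _, _, a in specs],
        }
    )


class TestHourlyStress:
    def test_full_hour_all_stressed(self):
        # 20 samples of score 60 fill the 8:30-9:30 bin
        samples = sample_frame([(510 + 3 * i, 60, False) for i in range(20)])
        out = hs.hourly_stress(samples)
        assert len(out) == 1
        assert out["valid_minutes"].iloc[0] == pytest.approx(60)
        assert out["stress_minutes"].iloc[0] == pytest.approx(60)
        assert out["stress_fraction"].iloc[0] == pytest.approx(1.0)

    def test_mixed_scores(self):
        specs = [(510 + 3 * i, 70, False) for i in range(4)]
        specs += [(510 + 3 * i, 30, False) for i in range(4, 10)]
        out = hs.hourly_stress(sample_frame(specs))
        assert out["valid_minutes"].iloc[0] == pytest.approx(30)
        assert out["stress_minutes"].iloc[0] == pytest.approx(12)
        assert out["stress_fraction"].iloc[0] == pytest.approx(0.4)

    def test_activity_and_missing_invalid(self):
        specs = [(510, 60, True), (513, np.nan, False), (516, 60, False)]
        out = hs.hourly_stress(sample_frame(specs))
        assert out["valid_minutes"].iloc[0] == pytest.approx(3)

    def test_edge_sample_clipped_across_bins(self):
        # sample at 9:28 covers 9:28-9:31, straddling the :30 anchor
        out = hs.hourly_stress(sample_frame([(568, 60, False)]))
        assert len(out) == 2
        assert out["valid_minutes"].tolist() == pytest.approx([2.0, 1.0])

    def test_matches_minute_grid_oracle(self, rng):
        # random 3-min grid with dropout vs per-minute brute force
        minutes = np.arange(0, 24 * 60, 3)
        keep = rng.random(len(minutes)) < 0.7
        scores = rng.integers(0, 101, size=len(minutes))
        specs = [(int(m), int(s), False) for m, s, k in zip(minutes, scores, keep) if k]
        out = hs.hourly_stress(sample_frame(specs))
        grid_valid = np.zeros(24 * 60 + 3)
        grid_stress = np.zeros(24 * 60 + 3)
        for m, s, _ in specs:
            grid_valid[m : m + 3] = 1
            grid_stress[m : m + 3] = 1 if s > 50 else 0
        assert out["valid_minutes"].sum() == pytest.approx(grid_valid.sum())
        assert out["stress_minutes"].sum() == pytest.approx(grid_stress.sum())

    def test_stress_never_exceeds_valid(self, small_cohort):
        out = hs.hourly_stress(small_cohort.stress)
        assert (out["stress_minutes"] <= out["valid_minutes"] + 1e-9).all()
        frac = out["stress_fraction"].dropna()
        assert ((frac >= 0) & (frac <= 1)).all()


class TestStressFraction:
    @pytest.mark.parametrize(
        "stress,valid,expect", [(80, 243, 33), (47, 265, 18), (0, 100, 0)]
    )
    def test_reported_percentages(self, stress, valid, expect):
        assert hs.round_percent(hs.stress_fraction(stress, valid)) == expect

    def test_zero_valid_missing(self):
        assert np.isnan(hs.stress_fraction(10, 0))


class TestValidityFilters:
    def test_removal_report_percentage(self):
        valid = np.full(4245, 45.0)
        valid[:1177] = 10.0
        hourly = pd.DataFrame(
            {
                "physician_id": "P0",
                "bin_start": pd.date_range("2023-03-06", periods=4245, freq="h"),
                "valid_minutes": valid,
                "stress_minutes": 0.0,
                "stress_fraction": 0.0,
            }
        )
        kept, _, report = hs.apply_validity_filters(hourly)
        assert len(kept) == 4245 - 1177
        assert report[0].as_dict()["percent_removed"] == 27.73

    def test_all_valid_nothing_removed(self):
        hourly = pd.DataFrame(
            {
                "physician_id": "P0",
                "bin_start": pd.date_range("2023-03-06", periods=10, freq="h"),
                "valid_minutes": 30.0,
                "stress_minutes": 3.0,
                "stress_fraction": 0.1,
            }
        )
        kept, _, report = hs.apply_validity_filters(hourly)
        assert report[0].removed == 0 and len(kept) == 10

    def test_filter_idempotent(self, small_cohort):
        hourly = hs.hourly_stress(small_cohort.stress)
        once, _, _ = hs.apply_validity_filters(hourly)
        twice, _, rep = hs.apply_validity_filters(once)
        assert len(twice) == len(once) and rep[0].removed == 0

    def test_random_dropout_matches_brute_force(self, rng):
        valid = rng.uniform(0, 60, size=500)
        hourly = pd.DataFrame(
            {
                "physician_id": "P0",
                "bin_start": pd.date_range("2023-03-06", periods=500, freq="h"),
                "valid_minutes": valid,
                "stress_minutes": 0.0,
                "stress_fraction": 0.0,
            }
        )
        kept, _, report = hs.apply_validity_filters(hourly)
        assert report[0].removed == int((valid < 20).sum())
        assert len(kept) == int((valid >= 20).sum())

    def test_day_filter_thresholds(self):
        daily = pd.DataFrame(
            {
                "physician_id": ["P0", "P0"],
                "date": pd.to_datetime(["2023-03-06", "2023-03-07"]),
                "valid_minutes": [200.0, 60.0],
                "stress_minutes": [10.0, 5.0],
                "stress_fraction": [0.05, 0.08],
            }
        )
        hourly = pd.DataFrame(columns=["physician_id", "bin_start", "valid_minutes"])
        hourly["valid_minutes"] = hourly["valid_minutes"].astype(float)
        _, days, report = hs.apply_validity_filters(hourly.assign(stress_minutes=0.0), daily)
        assert len(days) == 1 and report[1].removed == 1


class TestDailyCurve:
    def test_constant_fraction_single_physician(self):
        hourly = pd.DataFrame(
            {
                "physician_id": "P0",
                "bin_start": pd.to_datetime(["2023-03-06 08:30", "2023-03-07 08:30"]),
                "valid_minutes": 60.0,
                "stress_minutes": 18.0,
                "stress_fraction": 0.3,
            }
        )
        curve = hs.daily_stress_curve(hourly)
        assert curve["mean"].iloc[0] == pytest.approx(0.30)
        assert curve["sd"].iloc[0] == pytest.approx(0.0)

    def test_two_point_sd_closed_form(self):
        hourly = pd.DataFrame(
            {
                "physician_id": ["P0", "P1"],
                "bin_start": pd.to_datetime(["2023-03-06 08:30"] * 2),
                "valid_minutes": 60.0,
                "stress_minutes": [12.0, 24.0],
                "stress_fraction": [0.2, 0.4],
            }
        )
        curve = hs.daily_stress_curve(hourly)
        assert curve["mean"].iloc[0] == pytest.approx(0.30)
        assert curve["sd"].iloc[0] == pytest.approx(np.sqrt(((0.2 - 0.3) ** 2 + (0.4 - 0.3) ** 2) / 1), abs=1e-9)
        assert curve["se"].iloc[0] == pytest.approx(curve["sd"].iloc[0] / np.sqrt(2))


def test_work_hours_daily_rollup(small_cohort):
    hourly = hs.hourly_stress(small_cohort.stress)
    kept, _, _ = hs.apply_validity_filters(hourly)
    wh = hs.daily_stress(kept, work_hours_only=True)
    allday = hs.daily_stress(kept)
    merged = wh.merge(allday, on=["physician_id", "date"], suffixes=("_wh", "_all"))
    assert (merged["valid_minutes_wh"] <= merged["valid_minutes_all"] + 1e-9).all()
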