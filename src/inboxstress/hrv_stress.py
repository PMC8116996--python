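"""Validity-filtered stress-duration measures from 3-minute HRV stress scores.

A wrist wearable emits a 0–100 stress score as a 3-minute average, computed
from heart-rate variability in still moments.  Scores above 50 mark medium
or high stress; 25–50 is low stress (normal arousal, counted as valid but
not stressful); below 25 is rest.  Samples taken during registered physical
activity, and gaps where the device was off, contribute no valid minutes.

The analysis unit is the *stress duration*: minutes of medium/high stress
within a measurement period of valid minutes.  Hours with fewer than 20
valid minutes and days with fewer than 120 are excluded so that stress
fractions are not computed on sparse denominators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .log_features import bin_index, bin_start

SAMPLE_MINUTES = 3.0


@dataclass(frozen=True)
class StressBands:
    """Score bands: > medium_high_threshold is stress; low_band is valid, not stress."""

    medium_high_threshold: float = 50.0
    low_band: tuple[float, float] = (25.0, 50.0)


@dataclass(frozen=True)
class ValidityThresholds:
    """Minimum valid minutes for an hour / a day to enter analyses."""

    min_valid_minutes_hour: float = 20.0
    min_valid_minutes_day: float = 120.0

    def __post_init__(self) -> None:
        if self.min_valid_minutes_hour <= 0 or self.min_valid_minutes_day <= 0:
            raise ValueError("validity thresholds must be positive")


def read_stress_samples(path) -> pd.DataFrame:
    """CSV with columns timestamp, physician_id, score, activity_flag."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    need = {"timestamp", "physician_id", "score", "activity_flag"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"stress sample file missing columns: {sorted(missing)}")
    present = df["score"].notna()
    if ((df.loc[present, "score"] < 0) | (df.loc[present, "score"] > 100)).any():
        raise ValueError("stress scores must be in [0, 100]")
    df["activity_flag"] = df["activity_flag"].astype(bool)
    return df


def write_stress_samples(samples: pd.DataFrame, path) -> None:
    out = samples.copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def hourly_stress(
    samples: pd.DataFrame,
    bands: StressBands | None = None,
    bin_anchor_min: int = 30,
) -> pd.DataFrame:
    """Aggregate 3-minute samples into per-physician hourly summaries.

    A sample covers ``[t, t+3min)`` and is classified all-or-nothing by its
    average score.  Samples with a missing score or an activity flag
    contribute no valid minutes.  A sample straddling an hour boundary is
    clipped, splitting its minutes across both bins.

    Returns columns ``physician_id, bin_start, valid_minutes,
    stress_minutes, stress_fraction`` (fraction NaN when no valid minutes).
    """
    bands = bands or StressBands()
    cols = ["physician_id", "bin_start", "valid_minutes", "stress_minutes", "stress_fraction"]
    if samples.empty:
        return pd.DataFrame(columns=cols)
    ok = samples["score"].notna() & ~samples["activity_flag"]
    s = samples[ok]
    if s.empty:
        return pd.DataFrame(columns=cols)
    t0 = s["timestamp"].to_numpy()
    t1 = t0 + np.timedelta64(int(SAMPLE_MINUTES * 60), "s")
    stressed = (s["score"].to_numpy() > bands.medium_high_threshold)

    i0 = bin_index(t0, bin_anchor_min)
    i1 = bin_index(t1 - np.timedelta64(1, "us"), bin_anchor_min)
    n = (i1 - i0 + 1).astype(np.int64)
    rep = np.repeat(np.arange(len(s)), n)
    offs = np.arange(n.sum()) - np.repeat(np.cumsum(n) - n, n)
    piece_bin = i0[rep] + offs
    bstart = bin_start(piece_bin, bin_anchor_min)
    bend = bstart + np.timedelta64(1, "h")
    minutes = (
        np.minimum(t1[rep], bend) - np.maximum(t0[rep], bstart)
    ) / np.timedelta64(1, "m")

    out = pd.DataFrame(
        {
            "physician_id": s["physician_id"].to_numpy()[rep],
            "bin_start": bstart,
            "valid_minutes": minutes,
            "stress_minutes": np.where(stressed[rep], minutes, 0.0),
        }
    )
    out = out.groupby(["physician_id", "bin_start"], as_index=False).sum()
    out["stress_fraction"] = np.where(
        out["valid_minutes"] > 0, out["stress_minutes"] / out["valid_minutes"], np.nan
    )
    return out.sort_values(["physician_id", "bin_start"]).reset_index(drop=True)


def stress_fraction(stress_minutes: float, valid_minutes: float) -> float:
    """Stress duration as a percentage of valid minutes (NaN if none)."""
    if valid_minutes <= 0:
        return float("nan")
    return 100.0 * stress_minutes / valid_minutes


def round_percent(x: float) -> float:
    """Whole-percent, half-up rounding used in summary tables."""
    if math.isnan(x):
        return x
    return float(math.floor(x + 0.5))


def daily_stress(
    hourly: pd.DataFrame,
    schedule=None,
    work_hours_only: bool = False,
) -> pd.DataFrame:
    """Roll hourly summaries into per-physician-day valid/stress minutes.

    With ``work_hours_only`` the sum runs over shift-intersecting bins only
    (the work-hours stress duration outcome); otherwise over the whole day.
    Only hours in ``hourly`` contribute, so apply the hourly validity filter
    first when the analysis requires it.
    """
    if hourly.empty:
        return pd.DataFrame(
            columns=["physician_id", "date", "valid_minutes", "stress_minutes", "stress_fraction"]
        )
    h = hourly.copy()
    h["date"] = pd.to_datetime(h["bin_start"]).dt.normalize()
    if work_hours_only:
        from .temporal_patterns import WorkSchedule

        schedule = schedule or WorkSchedule()
        keep = np.zeros(len(h), dtype=bool)
        for i, (bs, d) in enumerate(zip(h["bin_start"], h["date"])):
            be = bs + pd.Timedelta(hours=1)
            keep[i] = any(bs < hi and be > lo for lo, hi in schedule.shift_intervals(d))
        h = h[keep]
    out = h.groupby(["physician_id", "date"], as_index=False)[
        ["valid_minutes", "stress_minutes"]
    ].sum()
    out["stress_fraction"] = np.where(
        out["valid_minutes"] > 0, out["stress_minutes"] / out["valid_minutes"], np.nan
    )
    return out


@dataclass(frozen=True)
class FilterStage:
    """One validity-filter stage of the removal report."""

    name: str
    total: int
    removed: int

    @property
    def percent_removed(self) -> float:
        return 100.0 * self.removed / self.total if self.total else 0.0

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "total": self.total,
            "removed": self.removed,
            "percent_removed": round(self.percent_removed, 2),
        }


def apply_validity_filters(
    hourly: pd.DataFrame,
    daily: pd.DataFrame | None = None,
    thresholds: ValidityThresholds | None = None,
    workday_flags: pd.Series | None = None,
    inbox_minutes: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None, list[FilterStage]]:
    """Apply the hourly (20 min) and daily (2 h) valid-data filters.

    Returns (retained hours, retained days or None, removal report).  When
    ``workday_flags`` / ``inbox_minutes`` are given (indexed like ``daily``),
    days that are not workdays or have no inbox activity are removed in the
    same stage as the daily valid-minute filter, mirroring the study's
    day-level exclusions.
    """
    thresholds = thresholds or ValidityThresholds()
    report: list[FilterStage] = []

    keep_h = hourly["valid_minutes"] >= thresholds.min_valid_minutes_hour
    report.append(FilterStage("hours_min_valid", int(len(hourly)), int((~keep_h).sum())))
    hours_out = hourly[keep_h].reset_index(drop=True)

    days_out = None
    if daily is not None:
        keep_d = daily["valid_minutes"] >= thresholds.min_valid_minutes_day
        if workday_flags is not None:
            keep_d &= workday_flags.to_numpy(dtype=bool)
        if inbox_minutes is not None:
            keep_d &= inbox_minutes.to_numpy() > 0
        report.append(FilterStage("days_min_valid", int(len(daily)), int((~keep_d).sum())))
        days_out = daily[keep_d].reset_index(drop=True)
    return hours_out, days_out, report


def daily_stress_curve(hourly: pd.DataFrame, bin_anchor_min: int = 30) -> pd.DataFrame:
    """Cohort mean stress fraction by clock hour, for the daily-wave plot.

    Input should already be validity-filtered.  For each clock bin (e.g.
    8:30–9:30) the mean, SD and SE of ``stress_fraction`` across all
    physician-hours are returned, with ``n`` the number of physician-hours.
    """
    if hourly.empty:
        return pd.DataFrame(columns=["clock_hour", "mean", "sd", "se", "n"])
    h = hourly.copy()
    bs = pd.to_datetime(h["bin_start"])
    h["clock_hour"] = bs.dt.hour + bs.dt.minute / 60.0
    g = h.groupby("clock_hour")["stress_fraction"]
    out = g.agg(mean="mean", sd="std", n="count").reset_index()
    out["sd"] = out["sd"].fillna(0.0)
    out["se"] = out["sd"] / np.sqrt(out["n"])
    return out[["clock_hour", "mean", "sd", "se", "n"]]
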