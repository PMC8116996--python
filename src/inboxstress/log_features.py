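"""Sessionize EHR access-log events and bin attributed time by hour.

Access logs record discrete timestamped interactions (an "event"), not
durations.  Time is attributed with a last-event-carried-forward rule: each
event opens an interval that ends at the next event for the same physician,
capped at an idle cutoff (default 5 minutes) — the standard audit-log
convention when vendor "active time" fields are unavailable.  Attributed
intervals are then split exactly across hourly bins anchored to the shift
start (default :30 past the hour, so bins run 8:30–9:30, 9:30–10:30, ...).

Canonical containers are pandas DataFrames:

``events``
    columns ``timestamp`` (datetime64), ``physician_id``, ``category``
    (INBOX / OTHER_EHR), ``message_type`` (PATIENT / RESULT / REQUEST /
    ADMIN / NONE; NONE iff OTHER_EHR), ``window_id``,
    ``is_task_completion`` (bool).

``intervals``
    columns ``physician_id, start, end, category, message_type``.

``hourly``
    one row per physician × hour bin with ``minutes_ehr``,
    ``minutes_inbox``, ``minutes_patient/result/request/admin``,
    ``n_tasks``, ``n_window_switches``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CATEGORIES = ("INBOX", "OTHER_EHR")
MESSAGE_TYPES = ("PATIENT", "RESULT", "REQUEST", "ADMIN")

EVENT_COLUMNS = [
    "timestamp",
    "physician_id",
    "category",
    "message_type",
    "window_id",
    "is_task_completion",
]


@dataclass(frozen=True)
class SessionizationConfig:
    """How inter-event time becomes attributed minutes.

    Parameters
    ----------
    idle_cutoff_min:
        Maximum minutes attributed to a single event; an event's interval
        ends at the next event or after this many minutes, whichever is
        sooner.  Must be positive.
    bin_anchor_min:
        Minute-of-hour at which hourly bins start.  30 aligns bins with an
        8:30 shift start (bins 8:30–9:30, ...).
    """

    idle_cutoff_min: float = 5.0
    bin_anchor_min: int = 30

    def __post_init__(self) -> None:
        if self.idle_cutoff_min <= 0:
            raise ValueError("idle_cutoff_min must be positive")
        if not 0 <= self.bin_anchor_min < 60:
            raise ValueError("bin_anchor_min must be in [0, 60)")


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    """Validate the event schema; returns the frame (possibly re-typed).

    Raises ``ValueError`` on missing columns, unknown categories, or
    violation of the coupling message_type == NONE <=> category == OTHER_EHR.
    """
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event frame missing columns: {missing}")
    events = events.copy()
    events["timestamp"] = pd.to_datetime(events["timestamp"])
    bad_cat = set(events["category"].unique()) - set(CATEGORIES)
    if bad_cat:
        raise ValueError(f"unknown categories: {sorted(bad_cat)}")
    bad_mt = set(events["message_type"].unique()) - set(MESSAGE_TYPES) - {"NONE"}
    if bad_mt:
        raise ValueError(f"unknown message types: {sorted(bad_mt)}")
    is_other = events["category"] == "OTHER_EHR"
    is_none = events["message_type"] == "NONE"
    if (is_other != is_none).any():
        raise ValueError("message_type must be NONE exactly when category is OTHER_EHR")
    events["is_task_completion"] = events["is_task_completion"].astype(bool)
    return events


def read_log_events(path) -> pd.DataFrame:
    """Read log events from CSV (or JSON lines if the suffix is .jsonl)."""
    path = str(path)
    if path.endswith(".jsonl") or path.endswith(".json"):
        events = pd.read_json(path, lines=True, convert_dates=["timestamp"])
    else:
        events = pd.read_csv(path, parse_dates=["timestamp"])
    return validate_events(events)


def write_log_events(events: pd.DataFrame, path) -> None:
    out = events.copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def sessionize(events: pd.DataFrame, cfg: SessionizationConfig | None = None) -> pd.DataFrame:
    """Turn timestamped events into attributed activity intervals.

    Each event opens an interval ``[t, min(t_next, t + idle_cutoff))`` where
    ``t_next`` is the next event of the *same physician*.  The final event of
    a physician's stream receives the full idle cutoff.  Zero-length
    intervals (tied timestamps) are dropped.

    Raises ``ValueError`` if events are not sorted by timestamp within
    physician.
    """
    cfg = cfg or SessionizationConfig()
    if events.empty:
        return pd.DataFrame(columns=["physician_id", "start", "end", "category", "message_type"])
    ts = events["timestamp"].to_numpy()
    pid = events["physician_id"].to_numpy()
    same = pid[1:] == pid[:-1]
    if np.any((ts[1:] < ts[:-1]) & same):
        raise ValueError("events must be sorted by timestamp within each physician")

    cutoff = np.timedelta64(int(round(cfg.idle_cutoff_min * 60_000_000)), "us")
    nxt = np.empty_like(ts)
    nxt[:-1] = np.where(same, ts[1:], ts[:-1] + cutoff)
    nxt[-1] = ts[-1] + cutoff
    end = np.minimum(nxt, ts + cutoff)

    intervals = pd.DataFrame(
        {
            "physician_id": pid,
            "start": ts,
            "end": end,
            "category": events["category"].to_numpy(),
            "message_type": events["message_type"].to_numpy(),
        }
    )
    return intervals[intervals["end"] > intervals["start"]].reset_index(drop=True)


def _bin_origin(anchor_min: int) -> pd.Timestamp:
    # any fixed instant at :anchor works as the binning origin
    return pd.Timestamp("2000-01-01 00:00:00") + pd.Timedelta(minutes=anchor_min)


def bin_index(ts: np.ndarray, anchor_min: int) -> np.ndarray:
    """Integer hour-bin index of each timestamp under the given anchor."""
    origin = np.datetime64(_bin_origin(anchor_min))
    return np.floor((ts - origin) / np.timedelta64(1, "h")).astype(np.int64)


def bin_start(idx: np.ndarray, anchor_min: int) -> np.ndarray:
    origin = np.datetime64(_bin_origin(anchor_min))
    return origin + idx * np.timedelta64(1, "h")


def bin_hourly(intervals: pd.DataFrame, cfg: SessionizationConfig | None = None) -> pd.DataFrame:
    """Split attributed intervals exactly across the hour bins they straddle.

    Returns a long frame ``physician_id, bin_start, category, message_type,
    minutes`` with one row per (interval × bin) piece; minutes are conserved
    to floating precision.  Bins with no activity are omitted.
    """
    cfg = cfg or SessionizationConfig()
    if intervals.empty:
        return pd.DataFrame(
            columns=["physician_id", "bin_start", "category", "message_type", "minutes"]
        )
    start = intervals["start"].to_numpy()
    end = intervals["end"].to_numpy()
    i0 = bin_index(start, cfg.bin_anchor_min)
    # half-open intervals: an end exactly on a boundary stays in the earlier bin
    i1 = bin_index(end - np.timedelta64(1, "us"), cfg.bin_anchor_min)
    n_bins = (i1 - i0 + 1).astype(np.int64)

    rep = np.repeat(np.arange(len(intervals)), n_bins)
    # offset of each piece within its interval's bin range
    offs = np.arange(n_bins.sum()) - np.repeat(np.cumsum(n_bins) - n_bins, n_bins)
    piece_bin = i0[rep] + offs
    bstart = bin_start(piece_bin, cfg.bin_anchor_min)
    bend = bstart + np.timedelta64(1, "h")
    piece_start = np.maximum(start[rep], bstart)
    piece_end = np.minimum(end[rep], bend)
    minutes = (piece_end - piece_start) / np.timedelta64(1, "m")

    out = pd.DataFrame(
        {
            "physician_id": intervals["physician_id"].to_numpy()[rep],
            "bin_start": bstart,
            "category": intervals["category"].to_numpy()[rep],
            "message_type": intervals["message_type"].to_numpy()[rep],
            "minutes": minutes,
        }
    )
    return (
        out.groupby(["physician_id", "bin_start", "category", "message_type"], as_index=False)[
            "minutes"
        ]
        .sum()
        .sort_values(["physician_id", "bin_start"])
        .reset_index(drop=True)
    )


def count_window_switches(
    events: pd.DataFrame, cfg: SessionizationConfig | None = None
) -> pd.DataFrame:
    """Per physician × hour bin count of window switches.

    A switch is an event whose ``window_id`` differs from the immediately
    preceding event of the same physician on the same calendar day; the
    first event of a physician-day counts zero.
    """
    cfg = cfg or SessionizationConfig()
    if events.empty:
        return pd.DataFrame(columns=["physician_id", "bin_start", "n_window_switches"])
    ts = events["timestamp"].to_numpy()
    pid = events["physician_id"].to_numpy()
    wid = events["window_id"].to_numpy()
    day = events["timestamp"].dt.normalize().to_numpy()
    switch = np.zeros(len(events), dtype=bool)
    same_run = (pid[1:] == pid[:-1]) & (day[1:] == day[:-1])
    switch[1:] = same_run & (wid[1:] != wid[:-1])
    out = pd.DataFrame(
        {
            "physician_id": pid,
            "bin_start": bin_start(bin_index(ts, cfg.bin_anchor_min), cfg.bin_anchor_min),
            "n_window_switches": switch.astype(np.int64),
        }
    )
    return out.groupby(["physician_id", "bin_start"], as_index=False)["n_window_switches"].sum()


def count_tasks(events: pd.DataFrame, cfg: SessionizationConfig | None = None) -> pd.DataFrame:
    """Per physician × hour bin count of task-completion markers."""
    cfg = cfg or SessionizationConfig()
    if events.empty:
        return pd.DataFrame(columns=["physician_id", "bin_start", "n_tasks"])
    out = pd.DataFrame(
        {
            "physician_id": events["physician_id"].to_numpy(),
            "bin_start": bin_start(
                bin_index(events["timestamp"].to_numpy(), cfg.bin_anchor_min),
                cfg.bin_anchor_min,
            ),
            "n_tasks": events["is_task_completion"].to_numpy().astype(np.int64),
        }
    )
    return out.groupby(["physician_id", "bin_start"], as_index=False)["n_tasks"].sum()


def build_hourly_usage(
    events: pd.DataFrame, cfg: SessionizationConfig | None = None
) -> pd.DataFrame:
    """Full hourly usage table: minutes by category/message type + counts.

    Columns: ``physician_id, bin_start, date, minutes_ehr, minutes_inbox,
    minutes_patient, minutes_result, minutes_request, minutes_admin,
    n_tasks, n_window_switches``.  Satisfies ``minutes_inbox <= minutes_ehr
    <= 60`` and ``sum(minutes_by_type) == minutes_inbox``.
    """
    cfg = cfg or SessionizationConfig()
    events = validate_events(events)
    intervals = sessionize(events, cfg)
    binned = bin_hourly(intervals, cfg)
    cols = [
        "minutes_ehr",
        "minutes_inbox",
        *[f"minutes_{t.lower()}" for t in MESSAGE_TYPES],
    ]
    if binned.empty:
        return pd.DataFrame(
            columns=["physician_id", "bin_start", "date", *cols, "n_tasks", "n_window_switches"]
        )

    key = ["physician_id", "bin_start"]
    ehr = binned.groupby(key, as_index=False)["minutes"].sum().rename(columns={"minutes": "minutes_ehr"})
    inbox = (
        binned[binned["category"] == "INBOX"]
        .groupby(key, as_index=False)["minutes"]
        .sum()
        .rename(columns={"minutes": "minutes_inbox"})
    )
    hourly = ehr.merge(inbox, on=key, how="left")
    for t in MESSAGE_TYPES:
        sub = (
            binned[binned["message_type"] == t]
            .groupby(key, as_index=False)["minutes"]
            .sum()
            .rename(columns={"minutes": f"minutes_{t.lower()}"})
        )
        hourly = hourly.merge(sub, on=key, how="left")
    hourly = hourly.merge(count_tasks(events, cfg), on=key, how="left")
    hourly = hourly.merge(count_window_switches(events, cfg), on=key, how="left")
    hourly = hourly.fillna(0.0)
    for c in ("n_tasks", "n_window_switches"):
        hourly[c] = hourly[c].astype(np.int64)
    hourly.insert(2, "date", pd.to_datetime(hourly["bin_start"]).dt.normalize())
    return hourly.sort_values(key).reset_index(drop=True)


def switching_rate(hourly: pd.DataFrame) -> float:
    """Window switches per minute of EHR use over the given hourly rows.

    Returns NaN when there are no EHR minutes.
    """
    total_min = float(hourly["minutes_ehr"].sum())
    if total_min <= 0:
        return float("nan")
    return float(hourly["n_window_switches"].sum()) / total_min


def time_per_message(hourly: pd.DataFrame, n_messages: int | None = None) -> float:
    """Minutes of inbox work per message handled.

    ``n_messages`` defaults to the number of task-completion markers in the
    rows (logs carry no message ids, so completed tasks proxy message
    count).  Returns NaN when no messages were handled.
    """
    if n_messages is None:
        n_messages = int(hourly["n_tasks"].sum())
    if n_messages <= 0:
        return float("nan")
    return float(hourly["minutes_inbox"].sum()) / n_messages


def write_hourly_csv(hourly: pd.DataFrame, path) -> None:
    """Tidy per-physician-hour CSV of hourly usage."""
    hourly.to_csv(path, index=False)
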