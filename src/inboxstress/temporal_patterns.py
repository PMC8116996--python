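"""Work-hours vs after-hours partition of inbox time and batching detection.

Inbox time on a workday is partitioned into three bins: minutes inside a
scheduled shift; after-hours minutes in an activity run adjoining a shift
boundary (within a configurable contiguity gap, default 60 min); and
after-hours minutes far from any shift (e.g. late evening).  The three
always sum to the day's inbox total.

A day's inbox work is *batched* when 70% or more of the day's inbox
duration falls in at most 3 blocks, where a block is a maximal set of inbox
intervals whose gaps do not exceed ``block_gap`` (default 15 min).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_SHIFTS = ((dt.time(8, 30), dt.time(12, 30)), (dt.time(13, 30), dt.time(17, 30)))


@dataclass(frozen=True)
class WorkSchedule:
    """Weekday shift schedule; weekdays without shifts are nonworkdays.

    ``shifts`` maps weekday index (Monday=0) to ordered, non-overlapping
    (start, end) clock intervals.  The default is Monday–Friday
    08:30–12:30 and 13:30–17:30.
    """

    shifts: dict = field(
        default_factory=lambda: {d: DEFAULT_SHIFTS for d in range(5)}
    )

    def __post_init__(self) -> None:
        for day, ivs in self.shifts.items():
            prev_end = dt.time(0, 0)
            for s, e in ivs:
                if not (prev_end <= s < e):
                    raise ValueError(f"shifts for weekday {day} must be ordered, non-overlapping")
                prev_end = e

    def is_workday(self, date) -> bool:
        return bool(self.shifts.get(pd.Timestamp(date).weekday(), ()))

    def shift_intervals(self, date) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
        """Absolute shift intervals for a calendar date (empty on nonworkdays)."""
        date = pd.Timestamp(date).normalize()
        out = []
        for s, e in self.shifts.get(date.weekday(), ()):
            out.append(
                (
                    date + pd.Timedelta(hours=s.hour, minutes=s.minute),
                    date + pd.Timedelta(hours=e.hour, minutes=e.minute),
                )
            )
        return out


@dataclass(frozen=True)
class TemporalSplit:
    """Partition of one day's inbox minutes; fields sum to the total."""

    in_hours_min: float
    contiguous_after_min: float
    noncontiguous_after_min: float

    @property
    def total_min(self) -> float:
        return self.in_hours_min + self.contiguous_after_min + self.noncontiguous_after_min

    @property
    def proportions(self) -> tuple[float, float, float]:
        """(in_hours, contiguous, noncontiguous) shares; NaNs if no inbox time."""
        tot = self.total_min
        if tot <= 0:
            return (float("nan"),) * 3
        return (
            self.in_hours_min / tot,
            self.contiguous_after_min / tot,
            self.noncontiguous_after_min / tot,
        )


@dataclass(frozen=True)
class BatchingConfig:
    """Batching rule: >=coverage_threshold of inbox time in <=max_blocks blocks."""

    block_gap_min: float = 15.0
    coverage_threshold: float = 0.70
    max_blocks: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.coverage_threshold <= 1:
            raise ValueError("coverage_threshold must be in (0, 1]")
        if self.max_blocks < 1:
            raise ValueError("max_blocks must be >= 1")
        if self.block_gap_min < 0:
            raise ValueError("block_gap_min must be >= 0")


def _overlap_minutes(starts, ends, lo, hi) -> np.ndarray:
    a = np.maximum(starts, np.datetime64(lo))
    b = np.minimum(ends, np.datetime64(hi))
    return np.maximum((b - a) / np.timedelta64(1, "m"), 0.0)


def split_by_work_hours(
    intervals: pd.DataFrame,
    schedule: WorkSchedule | None = None,
    contiguity_gap_min: float = 60.0,
) -> TemporalSplit:
    """Partition one day's inbox intervals by relation to the shift schedule.

    ``intervals`` must be the inbox intervals of a single physician-day
    (columns ``start``, ``end``).  Minutes inside any shift are in-hours.
    Outside-shift minutes are *contiguous* when their activity run — inbox
    intervals merged across gaps of at most ``contiguity_gap_min`` — comes
    within ``contiguity_gap_min`` of a shift boundary, else *noncontiguous*.
    On a nonworkday everything outside (empty) shifts is noncontiguous.
    """
    schedule = schedule or WorkSchedule()
    if intervals.empty:
        return TemporalSplit(0.0, 0.0, 0.0)
    intervals = intervals.sort_values("start")
    starts = intervals["start"].to_numpy()
    ends = intervals["end"].to_numpy()
    day = pd.Timestamp(starts.min()).normalize()
    shifts = schedule.shift_intervals(day)

    total = float(((ends - starts) / np.timedelta64(1, "m")).sum())
    in_hours = float(sum(_overlap_minutes(starts, ends, lo, hi).sum() for lo, hi in shifts))

    # merge into activity runs across gaps <= contiguity gap
    gap = np.timedelta64(int(contiguity_gap_min * 60), "s")
    new_run = np.ones(len(starts), dtype=bool)
    run_end = ends[0]
    run_ids = np.zeros(len(starts), dtype=np.int64)
    rid = 0
    for i in range(1, len(starts)):
        if starts[i] - run_end <= gap:
            new_run[i] = False
        else:
            rid += 1
        run_end = max(run_end, ends[i])
        run_ids[i] = rid

    contiguous = 0.0
    for r in range(rid + 1):
        sel = run_ids == r
        r_start, r_end = starts[sel].min(), ends[sel].max()
        outside = float(((ends[sel] - starts[sel]) / np.timedelta64(1, "m")).sum()) - float(
            sum(_overlap_minutes(starts[sel], ends[sel], lo, hi).sum() for lo, hi in shifts)
        )
        if outside <= 0:
            continue
        near = False
        for lo, hi in shifts:
            # distance between the run and the shift interval
            d = max(
                (np.datetime64(lo) - r_end) / np.timedelta64(1, "m"),
                (r_start - np.datetime64(hi)) / np.timedelta64(1, "m"),
                0.0,
            )
            if d <= contiguity_gap_min:
                near = True
                break
        if near:
            contiguous += outside
    noncontiguous = max(total - in_hours - contiguous, 0.0)
    return TemporalSplit(in_hours, contiguous, noncontiguous)


def detect_blocks(inbox_intervals: pd.DataFrame, cfg: BatchingConfig | None = None) -> pd.DataFrame:
    """Merge inbox intervals with gaps <= block_gap into work blocks.

    Returns a frame ``start, end, inbox_minutes`` (block span and summed
    member-interval minutes), ordered by start.
    """
    cfg = cfg or BatchingConfig()
    if inbox_intervals.empty:
        return pd.DataFrame(columns=["start", "end", "inbox_minutes"])
    iv = inbox_intervals.sort_values("start")
    starts = iv["start"].to_numpy()
    ends = iv["end"].to_numpy()
    gap = np.timedelta64(int(cfg.block_gap_min * 60), "s")

    rows = []
    b_start, b_end = starts[0], ends[0]
    b_min = float((ends[0] - starts[0]) / np.timedelta64(1, "m"))
    for i in range(1, len(starts)):
        if starts[i] - b_end <= gap:
            b_end = max(b_end, ends[i])
        else:
            rows.append((b_start, b_end, b_min))
            b_start, b_end, b_min = starts[i], ends[i], 0.0
        b_min += float((ends[i] - starts[i]) / np.timedelta64(1, "m"))
    rows.append((b_start, b_end, b_min))
    return pd.DataFrame(rows, columns=["start", "end", "inbox_minutes"])


def is_batched_day(blocks: pd.DataFrame, cfg: BatchingConfig | None = None) -> bool:
    """True iff the top ``max_blocks`` blocks cover >= the coverage threshold.

    Empty days (no inbox time) are never batched.
    """
    cfg = cfg or BatchingConfig()
    if blocks.empty:
        return False
    minutes = np.sort(blocks["inbox_minutes"].to_numpy())[::-1]
    total = minutes.sum()
    if total <= 0:
        return False
    return bool(minutes[: cfg.max_blocks].sum() >= cfg.coverage_threshold * total)
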