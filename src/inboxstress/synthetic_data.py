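"""Seeded generator of physician cohorts: roster, EHR logs, stress series.

The generator emulates the data sources the analysis consumes, with the
statistical structure the study design assumes:

- three work-pattern group prototypes (work-hours / contiguous /
  noncontiguous inbox-time shares, daily inbox minutes, message-type mix,
  time per message, batching propensity, work-hours stress level), with
  group sizes 10/17/20;
- per-physician temporal-split proportions drawn on the 3-simplex by a
  moment-matched logistic-normal, honoring both the simplex constraint and
  the configured group dispersions;
- event streams laid out as contiguous activity runs whose sessionized
  duration equals the placed block durations (the generator knows the
  attribution rule: runs are separated by at least the idle cutoff and the
  final event of a run is placed one cutoff before the run end);
- a 3-wave daily stress-probability curve (morning / early-afternoon /
  evening Gaussian bumps over clock time with a night dip, squashed
  through a logistic link) with physician-level random intercepts,
  calibrated so each group hits its configured work-hours stress fraction
  and the cohort hits the configured first-work-hour mean;
- sensor dropout in contiguous device-off episodes, plus a configurable
  number of physicians with total device failure.

All randomness flows from a single integer seed; identical seeds yield
byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize, special

from .log_features import MESSAGE_TYPES

SHIFT_WINDOWS_MIN = ((510.0, 750.0), (810.0, 1050.0))  # 8:30-12:30, 13:30-17:30
IDLE_CUTOFF_MIN = 5.0
MIN_SEGMENT_MIN = 6.0  # shortest standalone activity piece the layout places


@dataclass(frozen=True)
class GroupPrototype:
    """Calibration targets for one inbox work-pattern group.

    Proportions are shares of all-day inbox duration in the order
    (work hours, contiguous after hours, noncontiguous after hours).
    """

    label: int
    n_physicians: int
    prop_mean: tuple  # (in_hours, contiguous, noncontiguous)
    prop_sd: tuple
    daily_inbox_mean: float  # workday inbox minutes
    daily_inbox_sd: float
    nonworkday_inbox_mean: float
    nonworkday_inbox_sd: float
    message_mix: tuple  # PATIENT, RESULT, REQUEST, ADMIN shares
    time_per_message_mean: float
    time_per_message_sd: float
    batching_prob: float
    work_stress_frac_mean: float
    work_stress_frac_sd: float

    def __post_init__(self) -> None:
        if abs(sum(self.prop_mean) - 1.0) > 0.02:
            raise ValueError("prop_mean must sum to ~1")
        if abs(sum(self.message_mix) - 1.0) > 0.02:
            raise ValueError("message_mix must sum to ~1")
        if min(self.prop_sd) < 0 or self.daily_inbox_sd < 0:
            raise ValueError("SDs must be nonnegative")


# Reference group-level descriptives of the emulated study cohort.
STUDY_PROTOTYPES: tuple[GroupPrototype, ...] = (
    GroupPrototype(
        label=1,
        n_physicians=10,
        prop_mean=(0.37, 0.21, 0.42),
        prop_sd=(0.12, 0.11, 0.11),
        daily_inbox_mean=25.36 + 41.37,
        daily_inbox_sd=19.0,
        nonworkday_inbox_mean=32.74,
        nonworkday_inbox_sd=37.46,
        message_mix=(0.32, 0.30, 0.24, 0.14),
        time_per_message_mean=0.46,
        time_per_message_sd=0.11,
        batching_prob=0.50,
        work_stress_frac_mean=0.33,
        work_stress_frac_sd=0.27,
    ),
    GroupPrototype(
        label=2,
        n_physicians=17,
        prop_mean=(0.82, 0.17, 0.01),
        prop_sd=(0.08, 0.07, 0.02),
        daily_inbox_mean=47.97 + 10.91,
        daily_inbox_sd=14.5,
        nonworkday_inbox_mean=11.13,
        nonworkday_inbox_sd=19.69,
        message_mix=(0.35, 0.32, 0.20, 0.13),
        time_per_message_mean=0.35,
        time_per_message_sd=0.06,
        batching_prob=0.06,
        work_stress_frac_mean=0.18,
        work_stress_frac_sd=0.18,
    ),
    GroupPrototype(
        label=3,
        n_physicians=20,
        prop_mean=(0.62, 0.26, 0.12),
        prop_sd=(0.09, 0.13, 0.05),
        daily_inbox_mean=42.13 + 26.97,
        daily_inbox_sd=21.2,
        nonworkday_inbox_mean=6.54,
        nonworkday_inbox_sd=11.3,
        message_mix=(0.42, 0.26, 0.21, 0.11),
        time_per_message_mean=0.38,
        time_per_message_sd=0.07,
        batching_prob=0.20,
        work_stress_frac_mean=0.22,
        work_stress_frac_sd=0.24,
    ),
)


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters of the generated cohort."""

    n_workdays: int = 5
    n_nonworkdays: int = 2
    start_date: str = "2023-03-06"  # a Monday
    total_ehr_mean_min: float = 210.0  # 3.5 h on workdays
    total_ehr_sd_min: float = 41.4  # SD 0.69 h
    nonworkday_other_ehr_mean_min: float = 10.0
    day_factor_sd: float = 0.15  # day-to-day multiplicative noise
    event_interval_s: float = 13.6  # ~4.4 events/min of EHR use
    switch_prob: float = 0.97  # P(new window id at an event)
    mix_concentration: float = 22.0  # Dirichlet spread of physician message mix
    # stress-curve shape: Gaussian bumps at morning / early afternoon / evening
    wave_centers_h: tuple = (9.0, 13.75, 20.0)
    wave_widths_h: tuple = (0.7, 0.9, 1.5)
    wave_rel_amps: tuple = (1.0, 0.55, 0.8)
    night_dip_amp: float = 1.2
    first_hour_stress_mean: float = 0.35
    stress_intercept_sd: float = 0.8
    activity_flag_prob: float = 0.04
    dropout_episodes_per_day: float = 2.0
    dropout_mean_min: float = 75.0
    # intermittent-contact episodes: device worn loosely, samples thinned
    poorwear_episodes_per_day: float = 3.0
    poorwear_mean_min: float = 90.0
    poorwear_keep_prob: float = 0.15
    day_nowear_prob: float = 0.15  # device forgotten / charging all day
    n_device_failures: int = 5

    def validate(self, prototypes) -> None:
        if self.n_workdays < 1 or self.n_nonworkdays < 0:
            raise ValueError("need at least one workday")
        if not 0 <= self.activity_flag_prob < 1:
            raise ValueError("activity_flag_prob must be in [0,1)")
        shift_capacity = sum(hi - lo for lo, hi in SHIFT_WINDOWS_MIN)
        for p in prototypes:
            in_hours = p.daily_inbox_mean * p.prop_mean[0]
            other = max(self.total_ehr_mean_min - p.daily_inbox_mean, 20.0)
            if in_hours + other > shift_capacity - 40.0:
                raise ValueError(
                    f"group {p.label}: configured in-hours activity exceeds shift capacity"
                )
            after_hours = p.daily_inbox_mean * (1.0 - p.prop_mean[0])
            if after_hours > 300.0:
                raise ValueError(
                    f"group {p.label}: after-hours inbox minutes exceed the evening window"
                )
        if self.total_ehr_mean_min > shift_capacity + 200:
            raise ValueError("total EHR time infeasible for the schedule")


@dataclass
class Cohort:
    """A generated cohort: roster, log events, stress samples, ground truth."""

    roster: pd.DataFrame
    events: pd.DataFrame
    stress: pd.DataFrame
    truth: dict
    seed: int


# ---------------------------------------------------------------------------
# logistic-normal moment matching on the 3-simplex


def _ln_chol(theta):
    mu = theta[:2]
    s1, s2 = np.exp(theta[2:4])
    rho = np.tanh(theta[4])
    L = np.array([[s1, 0.0], [rho * s2, s2 * np.sqrt(max(1 - rho**2, 1e-12))]])
    return mu, L


def _ln_moments(theta, z: np.ndarray, w: np.ndarray):
    """Mean/SD of the first two softmax components under a bivariate ALR normal."""
    mu, L = _ln_chol(theta)
    U1, U2 = np.meshgrid(np.sqrt(2.0) * z, np.sqrt(2.0) * z, indexing="ij")
    Y1 = mu[0] + L[0, 0] * U1
    Y2 = mu[1] + L[1, 0] * U1 + L[1, 1] * U2
    W = np.outer(w, w) / np.pi
    den = 1.0 + np.exp(Y1) + np.exp(Y2)
    p1 = np.exp(Y1) / den
    p2 = np.exp(Y2) / den
    m1, m2 = (W * p1).sum(), (W * p2).sum()
    v1 = (W * p1**2).sum() - m1**2
    v2 = (W * p2**2).sum() - m2**2
    return m1, m2, np.sqrt(max(v1, 0)), np.sqrt(max(v2, 0))


def match_logistic_normal(prop_mean, prop_sd, n_quad: int = 30):
    """Bivariate ALR-Gaussian parameters matching the first two component means/SDs.

    The third (reference) component is implied by the simplex constraint.
    The ALR coordinates ``log(p1/p3), log(p2/p3)`` carry a free
    correlation: with independent coordinates, a large variance in one
    share forces excess variance in the other through the shared
    denominator, so the configured dispersions are unreachable.  Returns
    (mu, L) with L the Cholesky factor of the ALR covariance.
    """
    m = np.asarray(prop_mean, dtype=float)
    s = np.asarray(prop_sd, dtype=float)
    z, w = np.polynomial.hermite.hermgauss(n_quad)
    target = np.array([m[0], m[1], max(s[0], 1e-3), max(s[1], 1e-3)])

    def resid(theta):
        got = np.array(_ln_moments(theta, z, w))
        return (got - target) / np.maximum(target, 1e-3)

    x0 = np.array(
        [
            np.log(max(m[0], 1e-3) / max(m[2], 1e-3)),
            np.log(max(m[1], 1e-3) / max(m[2], 1e-3)),
            np.log(max(s[0] / max(m[0] * (1 - m[0]), 1e-3), 0.05)),
            np.log(max(s[1] / max(m[1] * (1 - m[1]), 1e-3), 0.05)),
            0.0,
        ]
    )
    best = None
    for rho0 in (0.0, -1.0, 1.0):
        x0[4] = rho0
        sol = optimize.least_squares(resid, x0, xtol=1e-14, ftol=1e-14, max_nfev=600)
        if best is None or sol.cost < best.cost:
            best = sol
    return _ln_chol(best.x)


def draw_simplex_proportions(rng, prop_mean, prop_sd, size: int) -> np.ndarray:
    """Draw (size, 3) proportions via the moment-matched logistic-normal.

    Input/output order is (in-hours, contiguous, noncontiguous).  The
    contiguous share serves as the ALR reference, so the in-hours and
    noncontiguous means/SDs — the dimensions that separate the work
    patterns — are matched exactly and the contiguous dispersion is
    implied.
    """
    m = np.asarray(prop_mean, dtype=float)
    s = np.asarray(prop_sd, dtype=float)
    mu, L = match_logistic_normal(m[[0, 2, 1]], s[[0, 2, 1]])
    y = mu + rng.standard_normal((size, 2)) @ L.T
    e = np.exp(np.column_stack([y, np.zeros(size)]))
    p = e / e.sum(axis=1, keepdims=True)
    return p[:, [0, 2, 1]]


# ---------------------------------------------------------------------------
# stress-curve calibration

WORK_GRID_H = np.arange(8.5, 17.5, 0.05)
FIRST_HOUR_GRID_H = np.arange(8.5, 9.5, 0.05)


def stress_wave(t_hours: np.ndarray, cfg: CohortConfig) -> np.ndarray:
    """Unit-amplitude 3-wave logit shape over clock time."""
    t = np.asarray(t_hours, dtype=float)
    w = np.zeros_like(t)
    for c, width, a in zip(cfg.wave_centers_h, cfg.wave_widths_h, cfg.wave_rel_amps):
        w = w + a * np.exp(-((t - c) ** 2) / (2 * width**2))
    # circadian night dip centered at 3:00, wrapping midnight
    for c in (3.0, 27.0, -21.0):
        w = w - cfg.night_dip_amp * np.exp(-((t - c) ** 2) / (2 * 3.0**2))
    return w


def _mean_prob(c: float, scale: float, wvals: np.ndarray, sigma_u: float, z, w) -> float:
    """E over physician intercepts and the grid of sigmoid(c + scale*wave + u)."""
    u = np.sqrt(2.0) * sigma_u * z
    logits = c + scale * wvals[:, None] + u[None, :]
    return float((special.expit(logits) * (w / np.sqrt(np.pi))[None, :]).sum(axis=1).mean())


def calibrate_stress_curve(prototypes, cfg: CohortConfig) -> dict:
    """Solve group offsets and the wave amplitude for the configured targets.

    The amplitude ``scale`` is set so the cohort first-work-hour mean
    stress fraction equals ``cfg.first_hour_stress_mean`` while each group
    offset ``c_g`` holds that group's work-hours mean at its prototype
    value.  Deterministic (quadrature + root finding).
    """
    z, w = np.polynomial.hermite.hermgauss(20)
    w_work = stress_wave(WORK_GRID_H, cfg)
    w_first = stress_wave(FIRST_HOUR_GRID_H, cfg)
    sigma_u = cfg.stress_intercept_sd
    n_tot = sum(p.n_physicians for p in prototypes)

    def offsets(scale):
        out = {}
        for p in prototypes:
            out[p.label] = optimize.brentq(
                lambda c: _mean_prob(c, scale, w_work, sigma_u, z, w) - p.work_stress_frac_mean,
                -15, 10, xtol=1e-10,
            )
        return out

    def first_hour_gap(scale):
        cs = offsets(scale)
        m = sum(
            p.n_physicians * _mean_prob(cs[p.label], scale, w_first, sigma_u, z, w)
            for p in prototypes
        ) / n_tot
        return m - cfg.first_hour_stress_mean

    scale = optimize.brentq(first_hour_gap, 0.05, 8.0, xtol=1e-8)
    return {"scale": scale, "offsets": offsets(scale)}


# ---------------------------------------------------------------------------
# day layout: activity runs of (start, end, category) segments


def _truncnorm(rng, mean, sd, lo, hi, size=None):
    x = rng.normal(mean, sd, size=size)
    return np.clip(x, lo, hi)


def _censored_normal_loc(target_mean: float, sd: float, threshold: float) -> float:
    """Location so that a normal draw censored below ``threshold`` (to 0) has the target mean.

    Used for nonworkday inbox minutes, where many days have no inbox work
    at all: drawing N(loc, sd) and zeroing values under the threshold
    would otherwise inflate the mean above the configured value.
    """
    from scipy import stats as _st

    def mean_of(loc):
        a = (threshold - loc) / sd
        # E[X ; X >= threshold] for X ~ N(loc, sd)
        return loc * _st.norm.sf(a) + sd * _st.norm.pdf(a)

    if mean_of(target_mean) <= target_mean:  # already feasible at loc=target
        lo, hi = target_mean, target_mean + 10 * sd
    else:
        lo, hi = target_mean - 10 * sd, target_mean
    return float(optimize.brentq(lambda c: mean_of(c) - target_mean, lo, hi))


def _split_pieces(rng, total: float, n: int, min_piece: float) -> np.ndarray:
    """Split ``total`` into n pieces >= min_piece with Dirichlet weights."""
    n = max(1, min(n, int(total // min_piece) or 1))
    wts = rng.dirichlet(np.full(n, 4.0))
    pieces = min_piece + wts * (total - n * min_piece)
    if total < n * min_piece:  # degenerate: fewer/larger pieces
        return np.array([total])
    return pieces


def _layout_workday(rng, wh_inbox, contig, noncontig, other_ehr, batched):
    """Place one workday's activity as runs of contiguous segments.

    Returns a list of segments (start_min, end_min, category); segments of
    one run abut exactly, runs are separated by > idle cutoff.  Sessionized
    duration of a run equals its span (events are laid down accordingly).
    After-hours draws too short to stand as their own attributable block
    (< MIN_SEGMENT_MIN) are folded into the in-hours total so the day's
    inbox minutes are conserved.
    """
    segments = []
    # after-hours pieces shorter than a standalone block fold into their
    # neighbours: tiny noncontiguous minutes join the contiguous block
    # (both after hours, in-hours share untouched); a tiny contiguous
    # block becomes the tail of an inbox segment crossing the shift end.
    if 0 < noncontig < MIN_SEGMENT_MIN:
        contig += noncontig
        noncontig = 0.0
    boundary_ext = 0.0
    if 0 < contig < MIN_SEGMENT_MIN:
        if wh_inbox >= 2 * MIN_SEGMENT_MIN:
            boundary_ext = contig
            wh_inbox -= MIN_SEGMENT_MIN  # reserved for the crossing segment
        else:
            wh_inbox += contig
        contig = 0.0

    # cap in-shift activity so runs plus minimum gaps always fit the shifts
    shift_capacity = sum(hi - lo for lo, hi in SHIFT_WINDOWS_MIN)
    other_ehr = min(other_ehr, shift_capacity - 70.0 - wh_inbox)

    # in-hours: interleave other-EHR pieces with inbox snippets/blocks.
    # Other-EHR pieces stay >= 16 min so inbox snippets in consecutive runs
    # remain separate work blocks even on crowded days.
    n_other = max(min(8, int(other_ehr // 16.0)), 1)
    other_pieces = list(_split_pieces(rng, other_ehr, n_other, 16.0))
    if wh_inbox >= MIN_SEGMENT_MIN:
        n_in = 1 if batched else int(np.clip(wh_inbox // MIN_SEGMENT_MIN, 3, 10))
        inbox_pieces = list(_split_pieces(rng, wh_inbox, n_in, MIN_SEGMENT_MIN))
    elif wh_inbox > 0:
        inbox_pieces = [wh_inbox]  # short piece rides inside a run
    else:
        inbox_pieces = []

    runs = []  # each run: list of (duration, category)
    n_runs = max(len(other_pieces), len(inbox_pieces))
    for i in range(n_runs):
        run = []
        if i < len(inbox_pieces):
            run.append((inbox_pieces[i], "INBOX"))
        if i < len(other_pieces):
            run.append((other_pieces[i], "OTHER_EHR"))
        if run and run[-1][0] < IDLE_CUTOFF_MIN and len(run) > 1:
            run = run[::-1]  # keep the final segment >= the idle cutoff
        runs.append(run)
    rng.shuffle(runs)

    # distribute runs over the two shifts proportionally to capacity
    min_gap = 8.0
    shift_end = SHIFT_WINDOWS_MIN[-1][1]
    windows = [list(wi) for wi in SHIFT_WINDOWS_MIN]
    if boundary_ext > 0:  # reserve the afternoon tail for the crossing segment
        windows[-1][1] = shift_end - MIN_SEGMENT_MIN - min_gap
    durations = [sum(d for d, _ in r) for r in runs]
    caps = [hi - lo for lo, hi in windows]
    order = np.argsort(rng.random(len(runs)))
    assign = [[], []]
    load = [0.0, 0.0]
    for idx in order:
        s = 0 if (load[0] + durations[idx]) / caps[0] <= (load[1] + durations[idx]) / caps[1] else 1
        assign[s].append(idx)
        load[s] += durations[idx]
    for s, (lo, hi) in enumerate(windows):
        idxs = assign[s]
        if not idxs:
            continue
        used = sum(durations[i] for i in idxs)
        slack = (hi - lo) - used - min_gap * (len(idxs) + 1)
        if slack > 0:
            gaps = min_gap + rng.dirichlet(np.ones(len(idxs) + 1)) * slack
        else:
            # crowded day: shrink gaps; runs may merge but never overlap
            gaps = np.full(len(idxs) + 1, max(((hi - lo) - used) / (len(idxs) + 1), 0.2))
        t = lo + gaps[0]
        for k, i in enumerate(idxs):
            for dur, cat in runs[i]:
                segments.append((t, t + dur, cat))
                t += dur
            t += gaps[k + 1]

    # contiguous after-hours: run abutting (or crossing) the afternoon shift end
    contig_end = shift_end
    if boundary_ext > 0:
        segments.append((shift_end - MIN_SEGMENT_MIN, shift_end + boundary_ext, "INBOX"))
        contig_end = shift_end + boundary_ext
    if contig > 0:
        if not batched and contig >= 2 * MIN_SEGMENT_MIN + 2:
            # several blocks chained from the shift end with >block-gap
            # spacing; the chain merges into one shift-adjacent activity run
            pieces = _split_pieces(rng, contig, int(np.ceil(contig / 15.0)), MIN_SEGMENT_MIN)
            t = shift_end
            for piece in pieces:
                segments.append((t, t + piece, "INBOX"))
                t += piece + 17.0
            contig_end = t - 17.0
        else:
            segments.append((shift_end, shift_end + contig, "INBOX"))
            contig_end = shift_end + contig

    # noncontiguous: evening (and possibly early-morning) blocks far from shifts.
    # Non-batched days spread the evening over two blocks so that a heavy
    # after-hours day does not incidentally satisfy the batching rule.
    if noncontig > 0:
        morning = 0.0
        if (
            not batched
            and noncontig >= 4 * MIN_SEGMENT_MIN
            and (rng.random() < 0.35 or noncontig > 50.0)
        ):
            morning = min(noncontig * rng.uniform(0.25, 0.4), 40.0)
            segments.append((380.0, 380.0 + morning, "INBOX"))
        evening = noncontig - morning
        ev_start = max(1200.0, contig_end + 75.0)
        if not batched and evening >= 2 * MIN_SEGMENT_MIN + 2:
            # several modest evening checks, chained with >block-gap spacing;
            # the chain still merges into one noncontiguous activity run
            pieces = _split_pieces(rng, evening, int(np.ceil(evening / 12.0)), MIN_SEGMENT_MIN)
            t = ev_start
            for piece in pieces:
                segments.append((t, t + piece, "INBOX"))
                t += piece + 17.0
        elif evening > 0:
            segments.append((ev_start, ev_start + evening, "INBOX"))
    return sorted(segments)


def _layout_nonworkday(rng, inbox_min, other_min):
    segments = []
    if inbox_min > 0:
        if inbox_min >= 2 * MIN_SEGMENT_MIN + 2 and rng.random() < 0.5:
            a = float(rng.uniform(MIN_SEGMENT_MIN, inbox_min - MIN_SEGMENT_MIN))
            segments.append((600.0, 600.0 + a, "INBOX"))
            segments.append((900.0, 900.0 + (inbox_min - a), "INBOX"))
        else:
            segments.append((615.0, 615.0 + inbox_min, "INBOX"))
    if other_min > 0:
        segments.append((780.0, 780.0 + other_min, "OTHER_EHR"))
    return sorted(segments)


def _segments_to_runs(segments):
    """Group abutting segments (gap < idle cutoff) into runs."""
    runs = []
    cur = []
    for seg in segments:
        if cur and seg[0] - cur[-1][1] >= IDLE_CUTOFF_MIN:
            runs.append(cur)
            cur = []
        cur.append(seg)
    if cur:
        runs.append(cur)
    return runs


def _events_for_day(rng, segments, date, mix, n_messages, cfg: CohortConfig):
    """Lay event timestamps over the day's segments.

    Events fall on a jittered grid inside each segment, with an exact event
    at every segment start; the last event of each run sits one idle cutoff
    before the run end so the sessionized run duration equals its span.
    Each inbox segment carries one message type drawn from the physician's
    mix; ``n_messages`` task-completion markers are spread over inbox
    events.
    """
    step = cfg.event_interval_s / 60.0
    times, cats, mtypes = [], [], []
    for orig_run in _segments_to_runs(segments):
        run_start, run_end = orig_run[0][0], orig_run[-1][1]
        # last-event time fixed by the ORIGINAL run layout so the run's
        # sessionized span equals its design regardless of typing splits
        last_t = max(run_end - IDLE_CUTOFF_MIN, orig_run[-1][0])
        # an inbox segment handles several messages: split it into abutting
        # sub-segments of a few minutes, each carrying its own message type
        run = []
        for s, e, cat in orig_run:
            if cat == "INBOX" and e - s >= 8.0:
                k = min(int((e - s) // 4.0), 20)
                cuts = np.linspace(s, e, k + 1)
                run.extend((cuts[i], cuts[i + 1], cat) for i in range(k))
            else:
                run.append((s, e, cat))
        seg_types = {}
        for s, e, cat in run:
            mt = (
                str(rng.choice(MESSAGE_TYPES, p=mix)) if cat == "INBOX" else "NONE"
            )
            seg_types[s] = (cat, mt)
        bounds = np.array([s for s, _, _ in run])
        # event count targets the configured event rate over the full run
        # span (events stop one cutoff early, so density compensates)
        span = run_end - run_start
        n_extra = max(int(round(span / step)) - len(bounds) - 1, 0)
        extra = rng.uniform(run_start, last_t, size=n_extra)
        t = np.unique(np.concatenate([bounds[bounds <= last_t], extra, [last_t]]))
        t = t[(t >= run_start) & (t <= last_t)]
        seg_idx = np.searchsorted(bounds, t, side="right") - 1
        for ti, si in zip(t, seg_idx):
            cat, mt = seg_types[bounds[si]]
            times.append(ti)
            cats.append(cat)
            mtypes.append(mt)
    if not times:
        return pd.DataFrame(
            columns=["timestamp", "category", "message_type", "window_id", "is_task_completion"]
        )
    times = np.array(times)
    order = np.argsort(times, kind="stable")
    times, cats, mtypes = times[order], np.array(cats)[order], np.array(mtypes)[order]

    switches = rng.random(len(times)) < cfg.switch_prob
    switches[0] = True
    wid = np.cumsum(switches)
    is_inbox = cats == "INBOX"
    task = np.zeros(len(times), dtype=bool)
    n_inbox = int(is_inbox.sum())
    if n_inbox and n_messages > 0:
        pick = rng.choice(np.flatnonzero(is_inbox), size=min(n_messages, n_inbox), replace=False)
        task[pick] = True

    day0 = pd.Timestamp(date)
    ts = day0 + pd.to_timedelta(np.round(times * 60.0).astype(np.int64), unit="s")
    return pd.DataFrame(
        {
            "timestamp": ts,
            "category": cats,
            "message_type": mtypes,
            "window_id": [f"W{int(i):05d}" for i in wid],
            "is_task_completion": task,
        }
    )


def _stress_for_day(rng, date, c_phys, scale, cfg: CohortConfig):
    """3-minute stress samples for one day, thinned by device-off episodes."""
    t_min = np.arange(0.0, 24 * 60.0, 3.0)
    t_hours = t_min / 60.0
    p = special.expit(c_phys + scale * stress_wave(t_hours, cfg))
    stressed = rng.random(len(t_min)) < p
    score = np.where(
        stressed, rng.uniform(55.0, 95.0, len(t_min)), rng.uniform(5.0, 50.0, len(t_min))
    )
    activity = rng.random(len(t_min)) < cfg.activity_flag_prob

    keep = np.ones(len(t_min), dtype=bool)
    n_ep = rng.poisson(cfg.dropout_episodes_per_day)
    for _ in range(n_ep):
        start = rng.uniform(0.0, 24 * 60.0)
        length = rng.exponential(cfg.dropout_mean_min)
        keep &= ~((t_min >= start) & (t_min < start + length))
    # loose-contact episodes leave only scattered valid samples, producing
    # the sparse hours the 20-minute validity filter is meant to remove
    for _ in range(rng.poisson(cfg.poorwear_episodes_per_day)):
        start = rng.uniform(0.0, 24 * 60.0)
        length = rng.exponential(cfg.poorwear_mean_min)
        inside = (t_min >= start) & (t_min < start + length)
        keep &= ~inside | (rng.random(len(t_min)) < cfg.poorwear_keep_prob)
    day0 = pd.Timestamp(date)
    ts = day0 + pd.to_timedelta(t_min[keep].astype(np.int64), unit="m")
    return pd.DataFrame(
        {
            "timestamp": ts,
            "score": np.round(score[keep], 1),
            "activity_flag": activity[keep],
        }
    )


# ---------------------------------------------------------------------------


def generate_cohort(
    cfg: CohortConfig | None = None,
    prototypes: tuple[GroupPrototype, ...] = STUDY_PROTOTYPES,
    seed: int = 0,
) -> Cohort:
    """Generate a full synthetic cohort (roster, logs, stress, ground truth)."""
    cfg = cfg or CohortConfig()
    cfg.validate(prototypes)
    rng = np.random.default_rng(seed)
    start = pd.Timestamp(cfg.start_date)
    if start.weekday() != 0:
        raise ValueError("start_date must be a Monday")
    workdates = [start + pd.Timedelta(days=d) for d in range(cfg.n_workdays)]
    nonworkdates = [start + pd.Timedelta(days=5 + d) for d in range(cfg.n_nonworkdays)]

    calib = calibrate_stress_curve(prototypes, cfg)
    scale, offsets = calib["scale"], calib["offsets"]
    nw_locs = {
        p.label: _censored_normal_loc(
            p.nonworkday_inbox_mean, max(p.nonworkday_inbox_sd, 1e-6), MIN_SEGMENT_MIN
        )
        for p in prototypes
    }

    roster_rows, event_frames, stress_frames = [], [], []
    truth_phys = {}
    pid_counter = 0
    n_total = sum(p.n_physicians for p in prototypes)
    failure_ids = set()

    for proto in prototypes:
        props = draw_simplex_proportions(rng, proto.prop_mean, proto.prop_sd, proto.n_physicians)
        for k in range(proto.n_physicians):
            pid = f"P{pid_counter:03d}"
            pid_counter += 1
            p_in, p_con, p_non = props[k]
            daily_inbox = float(
                _truncnorm(rng, proto.daily_inbox_mean, proto.daily_inbox_sd, 15.0, 300.0)
            )
            total_ehr = float(
                _truncnorm(
                    rng, cfg.total_ehr_mean_min, cfg.total_ehr_sd_min, daily_inbox + 40.0, 460.0
                )
            )
            tpm = float(
                _truncnorm(
                    rng, proto.time_per_message_mean, proto.time_per_message_sd, 0.12, 1.5
                )
            )
            mix = rng.dirichlet(np.asarray(proto.message_mix) * cfg.mix_concentration)
            u = float(rng.normal(0.0, cfg.stress_intercept_sd))
            c_phys = offsets[proto.label] + u

            age = float(np.clip(rng.normal(43.83, 9.51), 31, 68))
            female = bool(rng.random() < 32 / 47)
            exp_years = float(np.clip(rng.normal(15.17, 9.93), 4, 42))
            fte = float(np.clip(rng.normal(0.81, 0.14), 0.5, 1.0))
            roster_rows.append(
                {
                    "physician_id": pid,
                    "group": proto.label,
                    "age": round(age, 1),
                    "sex": "F" if female else "M",
                    "years_experience": round(exp_years, 1),
                    "fte": round(fte, 2),
                }
            )

            day_truth = []
            nc_carry = 0.0  # small evening-work residue accumulates across days
            for date in workdates:
                f = float(np.clip(rng.normal(1.0, cfg.day_factor_sd), 0.5, 1.5))
                inbox_d = daily_inbox * f
                other_d = max((total_ehr - daily_inbox) * f, 20.0)
                batched = bool(rng.random() < proto.batching_prob)
                # a physician with a few noncontiguous minutes per day checks
                # the inbox on some evenings only: pool the minutes until
                # they form a placeable block
                noncontig_d = inbox_d * p_non + nc_carry
                last_workday = date == workdates[-1]
                if noncontig_d < MIN_SEGMENT_MIN and not last_workday:
                    nc_carry = noncontig_d
                    noncontig_d = 0.0
                else:
                    nc_carry = 0.0
                contig_d = inbox_d * p_con
                if 0 < noncontig_d < MIN_SEGMENT_MIN:
                    # week-end residue too small for an evening block joins
                    # the shift-adjacent work instead of being dropped
                    contig_d += noncontig_d
                    noncontig_d = 0.0
                segs = _layout_workday(
                    rng,
                    wh_inbox=inbox_d * p_in,
                    contig=contig_d,
                    noncontig=noncontig_d,
                    other_ehr=other_d,
                    batched=batched,
                )
                placed_inbox = sum(e - s for s, e, c in segs if c == "INBOX")
                n_msgs = max(int(round(placed_inbox / tpm)), 1)
                ev = _events_for_day(rng, segs, date, mix, n_msgs, cfg)
                ev.insert(1, "physician_id", pid)
                event_frames.append(ev)
                day_truth.append(
                    {
                        "date": str(date.date()),
                        "workday": True,
                        "inbox_minutes": round(placed_inbox, 3),
                        "other_ehr_minutes": round(
                            sum(e - s for s, e, c in segs if c == "OTHER_EHR"), 3
                        ),
                        "batched": batched,
                        "n_messages": n_msgs,
                    }
                )
            for date in nonworkdates:
                nw_inbox = float(rng.normal(nw_locs[proto.label], proto.nonworkday_inbox_sd))
                if nw_inbox < MIN_SEGMENT_MIN:
                    nw_inbox = 0.0
                nw_other = float(rng.normal(cfg.nonworkday_other_ehr_mean_min, 5.0))
                if nw_other < MIN_SEGMENT_MIN:
                    nw_other = 0.0
                segs = _layout_nonworkday(rng, nw_inbox, nw_other)
                n_msgs = max(int(round(nw_inbox / tpm)), 1) if nw_inbox > 0 else 0
                ev = _events_for_day(rng, segs, date, mix, n_msgs, cfg)
                if len(ev):
                    ev.insert(1, "physician_id", pid)
                    event_frames.append(ev)
                day_truth.append(
                    {
                        "date": str(date.date()),
                        "workday": False,
                        "inbox_minutes": round(nw_inbox, 3),
                        "other_ehr_minutes": round(nw_other, 3),
                        "batched": False,
                        "n_messages": n_msgs,
                    }
                )

            for date in [*workdates, *nonworkdates]:
                if rng.random() < cfg.day_nowear_prob:
                    continue
                sf = _stress_for_day(rng, date, c_phys, scale, cfg)
                sf.insert(1, "physician_id", pid)
                stress_frames.append(sf)

            truth_phys[pid] = {
                "group": proto.label,
                "prop_in_hours": round(float(p_in), 5),
                "prop_contiguous": round(float(p_con), 5),
                "prop_noncontiguous": round(float(p_non), 5),
                "daily_inbox_min": round(daily_inbox, 3),
                "total_ehr_min": round(total_ehr, 3),
                "time_per_message": round(tpm, 4),
                "message_mix": [round(float(x), 4) for x in mix],
                "stress_intercept": round(u, 4),
                "days": day_truth,
            }

    if cfg.n_device_failures:
        all_ids = sorted(truth_phys)
        failure_ids = set(
            rng.choice(all_ids, size=min(cfg.n_device_failures, n_total), replace=False)
        )

    events = (
        pd.concat(event_frames, ignore_index=True)
        .sort_values(["physician_id", "timestamp"], kind="stable")
        .reset_index(drop=True)
    )
    events = events[
        ["timestamp", "physician_id", "category", "message_type", "window_id", "is_task_completion"]
    ]
    stress = (
        pd.concat(stress_frames, ignore_index=True)
        .sort_values(["physician_id", "timestamp"], kind="stable")
        .reset_index(drop=True)
    )
    stress = stress[~stress["physician_id"].isin(failure_ids)].reset_index(drop=True)
    stress = stress[["timestamp", "physician_id", "score", "activity_flag"]]
    roster = pd.DataFrame(roster_rows)

    truth = {
        "seed": seed,
        "config": asdict(cfg),
        "stress_calibration": {
            "scale": round(scale, 6),
            "offsets": {str(k): round(v, 6) for k, v in offsets.items()},
        },
        "prototypes": [asdict(p) for p in prototypes],
        "device_failures": sorted(failure_ids),
        "physicians": truth_phys,
    }
    return Cohort(roster=roster, events=events, stress=stress, truth=truth, seed=seed)


def truth_manifest(cohort: Cohort) -> dict:
    """Ground-truth JSON manifest: the oracle for all recovery tests."""
    return cohort.truth


def write_cohort(cohort: Cohort, out_dir) -> dict:
    """Write the three CSV streams + truth JSON; returns the paths."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "events": out / "log_events.csv",
        "stress": out / "stress_samples.csv",
        "roster": out / "roster.csv",
        "truth": out / "truth.json",
    }
    ev = cohort.events.copy()
    ev["timestamp"] = ev["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    ev.to_csv(paths["events"], index=False)
    st = cohort.stress.copy()
    st["timestamp"] = st["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    st.to_csv(paths["stress"], index=False)
    cohort.roster.to_csv(paths["roster"], index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth, fh, indent=1, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
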