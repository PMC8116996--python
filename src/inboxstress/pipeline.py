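"""End-to-end orchestration: logs + stress -> features -> clusters -> model.

The pipeline wires the stage modules together on tidy DataFrames and
reports every filter stage (input n, removed n, %).  Stages can be used
individually; ``run_pipeline`` executes them all on a config and writes
plain CSV/JSON artifacts plus the two standard plots.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster_profiles, hrv_stress, log_features, stress_association, temporal_patterns
from .log_features import SessionizationConfig
from .temporal_patterns import BatchingConfig, WorkSchedule

MODEL_COVARIATES = [
    "fte",
    "age",
    "female",
    "switch_rate",
    "wh_inbox_min",
    "wh_other_ehr_min",
    "prop_outside",
    "patient_share",
    "batched",
]


@dataclass
class PipelineConfig:
    events_path: str | None = None
    stress_path: str | None = None
    roster_path: str | None = None
    out_dir: str | None = None
    seed: int = 0
    sessionization: SessionizationConfig = field(default_factory=SessionizationConfig)
    batching: BatchingConfig = field(default_factory=BatchingConfig)
    schedule: WorkSchedule = field(default_factory=WorkSchedule)
    thresholds: hrv_stress.ValidityThresholds = field(
        default_factory=hrv_stress.ValidityThresholds
    )
    contiguity_gap_min: float = 60.0
    cluster_K_values: tuple = (2, 3, 4)
    cluster_restarts: int = 10
    min_group_size: int = 5


def compute_day_features(
    events: pd.DataFrame,
    schedule: WorkSchedule | None = None,
    sess_cfg: SessionizationConfig | None = None,
    batch_cfg: BatchingConfig | None = None,
    contiguity_gap_min: float = 60.0,
) -> pd.DataFrame:
    """One row per physician-day of usage features.

    Columns: workday flag, EHR/inbox/other minutes, work-hours inbox and
    other-EHR minutes, temporal split (in/contiguous/noncontiguous),
    batching flag, switches, tasks, message-type minutes and patient
    share.
    """
    schedule = schedule or WorkSchedule()
    sess_cfg = sess_cfg or SessionizationConfig()
    batch_cfg = batch_cfg or BatchingConfig()
    events = log_features.validate_events(events)
    intervals = log_features.sessionize(events, sess_cfg)
    hourly = log_features.build_hourly_usage(events, sess_cfg)
    hourly["date"] = pd.to_datetime(hourly["bin_start"]).dt.normalize()

    rows = []
    intervals["date"] = pd.to_datetime(intervals["start"]).dt.normalize()
    for (pid, date), iv in intervals.groupby(["physician_id", "date"]):
        inbox_iv = iv[iv["category"] == "INBOX"]
        split = temporal_patterns.split_by_work_hours(
            inbox_iv, schedule, contiguity_gap_min=contiguity_gap_min
        )
        blocks = temporal_patterns.detect_blocks(inbox_iv, batch_cfg)
        batched = temporal_patterns.is_batched_day(blocks, batch_cfg)
        other_iv = iv[iv["category"] == "OTHER_EHR"]
        shifts = schedule.shift_intervals(date)
        wh_other = float(
            sum(
                temporal_patterns._overlap_minutes(
                    other_iv["start"].to_numpy(), other_iv["end"].to_numpy(), lo, hi
                ).sum()
                for lo, hi in shifts
            )
        ) if len(other_iv) else 0.0
        h = hourly[(hourly["physician_id"] == pid) & (hourly["date"] == date)]
        inbox_total = split.total_min
        type_min = {
            f"minutes_{t.lower()}": float(h[f"minutes_{t.lower()}"].sum())
            for t in log_features.MESSAGE_TYPES
        }
        rows.append(
            {
                "physician_id": pid,
                "date": date,
                "workday": schedule.is_workday(date),
                "minutes_ehr": float(h["minutes_ehr"].sum()),
                "minutes_inbox": float(h["minutes_inbox"].sum()),
                "in_hours_min": split.in_hours_min,
                "contiguous_after_min": split.contiguous_after_min,
                "noncontiguous_after_min": split.noncontiguous_after_min,
                "wh_inbox_min": split.in_hours_min,
                "wh_other_ehr_min": wh_other,
                "prop_outside": (
                    (split.contiguous_after_min + split.noncontiguous_after_min) / inbox_total
                    if inbox_total > 0
                    else 0.0
                ),
                "batched": float(batched),
                "n_blocks": int(len(blocks)),
                "n_tasks": int(h["n_tasks"].sum()),
                "n_window_switches": int(h["n_window_switches"].sum()),
                "switch_rate": (
                    float(h["n_window_switches"].sum() / h["minutes_ehr"].sum())
                    if h["minutes_ehr"].sum() > 0
                    else np.nan
                ),
                **type_min,
                "patient_share": (
                    type_min["minutes_patient"] / float(h["minutes_inbox"].sum())
                    if h["minutes_inbox"].sum() > 0
                    else np.nan
                ),
            }
        )
    return pd.DataFrame(rows).sort_values(["physician_id", "date"]).reset_index(drop=True)


def build_physician_profiles(
    day_features: pd.DataFrame, roster: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-physician feature vector for clustering and group comparison.

    Temporal-split proportions are means over workdays with any inbox
    time; batching fraction, time per message, patient share and
    nonworkday inbox minutes are attached as auxiliaries, plus
    demographics when a roster is given.
    """
    wd = day_features[(day_features["workday"]) & (day_features["minutes_inbox"] > 0)].copy()
    tot = wd[["in_hours_min", "contiguous_after_min", "noncontiguous_after_min"]].sum(axis=1)
    for col, name in [
        ("in_hours_min", "prop_in_hours"),
        ("contiguous_after_min", "prop_contiguous"),
        ("noncontiguous_after_min", "prop_noncontiguous"),
    ]:
        wd[name] = wd[col] / tot

    g = wd.groupby("physician_id")
    prof = g[["prop_in_hours", "prop_contiguous", "prop_noncontiguous"]].mean()
    prof["batching_fraction"] = g["batched"].mean()
    prof["time_per_message"] = g["minutes_inbox"].sum() / g["n_tasks"].sum()
    prof["patient_share"] = g["minutes_patient"].sum() / g["minutes_inbox"].sum()
    prof["daily_inbox_min"] = g["minutes_inbox"].mean()
    prof["daily_ehr_min"] = g["minutes_ehr"].mean()
    prof["switch_rate"] = g["n_window_switches"].sum() / g["minutes_ehr"].sum()

    nw = day_features[~day_features["workday"]]
    prof["nonworkday_inbox_min"] = (
        nw.groupby("physician_id")["minutes_inbox"].mean().reindex(prof.index).fillna(0.0)
    )
    if roster is not None:
        r = roster.set_index("physician_id")
        for c in ("age", "years_experience", "fte"):
            if c in r.columns:
                prof[c] = r[c]
        if "sex" in r.columns:
            prof["female"] = (r["sex"] == "F").astype(float)
    return prof.reset_index()


def summarize_descriptives(day_features: pd.DataFrame) -> dict:
    """Headline cohort descriptives (workday means across physicians)."""
    wd = day_features[day_features["workday"]]
    per_phys = wd.groupby("physician_id").agg(
        ehr_min=("minutes_ehr", "mean"), inbox_min=("minutes_inbox", "mean")
    )
    shares = {}
    for t in log_features.MESSAGE_TYPES:
        s = wd.groupby("physician_id").apply(
            lambda d, t=t: d[f"minutes_{t.lower()}"].sum() / max(d["minutes_inbox"].sum(), 1e-9),
            include_groups=False,
        )
        shares[t.lower()] = float(s.mean())
    total_share = sum(shares.values())
    nw = day_features[~day_features["workday"]]
    return {
        "mean_daily_ehr_hours": float(per_phys["ehr_min"].mean() / 60.0),
        "sd_daily_ehr_hours": float(per_phys["ehr_min"].std(ddof=1) / 60.0),
        "mean_daily_inbox_hours": float(per_phys["inbox_min"].mean() / 60.0),
        "sd_daily_inbox_hours": float(per_phys["inbox_min"].std(ddof=1) / 60.0),
        "message_share_percent": {k: 100.0 * v / total_share for k, v in shares.items()},
        "mean_nonworkday_inbox_min": (
            float(nw.groupby("physician_id")["minutes_inbox"].mean().mean()) if len(nw) else 0.0
        ),
        "mean_switch_rate_per_min": float(
            wd["n_window_switches"].sum() / wd["minutes_ehr"].sum()
        ),
    }


def missed_prompt_rate(n_missed: float, n_prompts: float) -> float:
    """Experience-sampling summary: percent of prompts missed."""
    if n_prompts <= 0:
        raise ValueError("n_prompts must be positive")
    return 100.0 * n_missed / n_prompts


def build_stress_day_table(
    stress: pd.DataFrame,
    day_features: pd.DataFrame,
    schedule: WorkSchedule | None = None,
    thresholds: hrv_stress.ValidityThresholds | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list]:
    """Hourly + daily stress with the study's validity and day filters.

    Returns (retained hours, physician-day model table, filter report).
    The model table carries work-hours stress minutes (integer counts),
    work-hours valid minutes as exposure, and the usage covariates.
    """
    schedule = schedule or WorkSchedule()
    thresholds = thresholds or hrv_stress.ValidityThresholds()
    hourly = hrv_stress.hourly_stress(stress)
    hours_kept, _, report = hrv_stress.apply_validity_filters(hourly, thresholds=thresholds)

    wh_daily = hrv_stress.daily_stress(hours_kept, schedule=schedule, work_hours_only=True)
    day_daily = hrv_stress.daily_stress(hours_kept, work_hours_only=False)
    merged = day_features.merge(
        wh_daily.rename(
            columns={"valid_minutes": "wh_valid_minutes", "stress_minutes": "wh_stress_minutes"}
        )[["physician_id", "date", "wh_valid_minutes", "wh_stress_minutes"]],
        on=["physician_id", "date"],
        how="left",
    ).merge(
        day_daily[["physician_id", "date", "valid_minutes"]], on=["physician_id", "date"], how="left"
    )
    merged["valid_minutes"] = merged["valid_minutes"].fillna(0.0)

    n0 = len(merged)
    keep = (
        (merged["valid_minutes"] >= thresholds.min_valid_minutes_day)
        & merged["workday"]
        & (merged["minutes_inbox"] > 0)
        & merged["wh_valid_minutes"].notna()
        & (merged["wh_valid_minutes"] > 0)
    )
    report.append(hrv_stress.FilterStage("days_valid_workday_inbox", n0, int((~keep).sum())))
    days = merged[keep].copy()
    days["stress_minutes"] = days["wh_stress_minutes"].round().astype(int)
    days = days.rename(columns={"wh_valid_minutes": "wh_valid"})
    days["valid_minutes_offset"] = days["wh_valid"]
    return hours_kept, days, report


def run_pipeline(
    cfg: PipelineConfig,
    events: pd.DataFrame | None = None,
    stress: pd.DataFrame | None = None,
    roster: pd.DataFrame | None = None,
) -> dict:
    """Execute all stages; returns a result dict and writes artifacts.

    Inputs may be passed in memory or read from the configured paths.  Any
    stage failure raises with the stage name in the message.
    """
    t0 = time.time()
    out = {"seed": cfg.seed, "stages": {}}

    def stage(name):
        out["stages"][name] = {"t_start": round(time.time() - t0, 2)}
        return name

    try:
        stage("ingest")
        if events is None:
            if cfg.events_path is None:
                raise ValueError("no events provided")
            events = log_features.read_log_events(cfg.events_path)
        if stress is None:
            if cfg.stress_path is None:
                raise ValueError("no stress samples provided")
            stress = hrv_stress.read_stress_samples(cfg.stress_path)
        if roster is None and cfg.roster_path is not None:
            roster = pd.read_csv(cfg.roster_path)
    except Exception as e:
        raise RuntimeError(f"[ingest] {e}") from e

    try:
        stage("features")
        day_features = compute_day_features(
            events, cfg.schedule, cfg.sessionization, cfg.batching, cfg.contiguity_gap_min
        )
        descriptives = summarize_descriptives(day_features)
    except Exception as e:
        raise RuntimeError(f"[features] {e}") from e

    try:
        stage("stress")
        hours_kept, model_days, filter_report = build_stress_day_table(
            stress, day_features, cfg.schedule, cfg.thresholds
        )
        curve = hrv_stress.daily_stress_curve(hours_kept)
    except Exception as e:
        raise RuntimeError(f"[stress] {e}") from e

    try:
        stage("cluster")
        profiles = build_physician_profiles(day_features, roster)
        chosen, selection_report = cluster_profiles.select_clustering(
            profiles,
            K_values=cfg.cluster_K_values,
            seed=cfg.seed,
            n_restarts=cfg.cluster_restarts,
            min_group_size=cfg.min_group_size,
        )
        comparison = cluster_profiles.compare_groups(
            profiles,
            chosen.assignments,
            continuous=[
                "prop_in_hours",
                "prop_contiguous",
                "prop_noncontiguous",
                "time_per_message",
                "patient_share",
                "nonworkday_inbox_min",
                "daily_inbox_min",
            ],
        )
    except Exception as e:
        raise RuntimeError(f"[cluster] {e}") from e

    try:
        stage("model")
        md = model_days.merge(
            profiles.set_index("physician_id")[["fte", "age", "female"]]
            if roster is not None
            else pd.DataFrame(index=profiles.set_index("physician_id").index),
            left_on="physician_id",
            right_index=True,
            how="left",
        )
        covs = [c for c in MODEL_COVARIATES if c in md.columns and md[c].notna().all()]
        frame, frame_info = stress_association.build_model_frame(
            md, covs, exposure="valid_minutes_offset"
        )
        fit = stress_association.fit_poisson_mixed(
            frame, frame_info["covariates"], exposure="valid_minutes_offset"
        )
    except Exception as e:
        raise RuntimeError(f"[model] {e}") from e

    out.update(
        {
            "descriptives": descriptives,
            "filter_report": [s.as_dict() for s in filter_report],
            "n_model_days": int(len(model_days)),
            "silhouette": chosen.silhouette,
            "group_sizes": {int(k): int(v) for k, v in chosen.group_sizes().items()},
            "model": {
                "aic": fit.aic,
                "r2_marginal": fit.r2_marginal,
                "r2_conditional": fit.r2_conditional,
                "converged": fit.converged,
                "sigma_b": fit.sigma_b,
            },
            "elapsed_s": round(time.time() - t0, 2),
        }
    )
    result = {
        "report": out,
        "day_features": day_features,
        "profiles": profiles,
        "clustering": chosen,
        "selection_report": selection_report,
        "comparison": comparison,
        "stress_curve": curve,
        "model_days": model_days,
        "model_fit": fit,
    }

    if cfg.out_dir is not None:
        _write_artifacts(cfg, result)
    return result


def _write_artifacts(cfg: PipelineConfig, result: dict) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result["day_features"].to_csv(out / "day_features.csv", index=False)
    result["profiles"].to_csv(out / "profiles.csv", index=False)
    result["clustering"].assignments.rename("group").to_csv(out / "cluster_assignments.csv")
    result["selection_report"].to_csv(out / "cluster_selection.csv", index=False)
    result["comparison"].drop(columns=["posthoc"]).to_csv(out / "group_comparison.csv", index=False)
    result["stress_curve"].to_csv(out / "stress_curve.csv", index=False)
    result["model_fit"].summary_frame().to_csv(out / "model_table.csv")
    with open(out / "run_report.json", "w") as fh:
        json.dump(result["report"], fh, indent=1, default=float)
    plot_stress_curve(result["stress_curve"], out / "stress_curve.png")
    plot_temporal_patterns(result["profiles"], result["clustering"], out / "temporal_patterns.png")


def plot_stress_curve(curve: pd.DataFrame, path) -> None:
    """Daily 3-wave stress plot: mean hourly stress fraction with SE bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    c = curve.sort_values("clock_hour")
    ax.errorbar(c["clock_hour"], 100 * c["mean"], yerr=100 * c["se"], marker="o", ms=3, lw=1)
    ax.axvspan(8.5, 12.5, color="green", alpha=0.1)
    ax.axvspan(13.5, 17.5, color="green", alpha=0.1)
    ax.set_xlabel("clock hour")
    ax.set_ylabel("stress duration (% of valid minutes)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_temporal_patterns(profiles: pd.DataFrame, clustering, path) -> None:
    """Per-group temporal-split profile bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    prof = profiles.set_index("physician_id")
    prof = prof.join(clustering.assignments.rename("group"))
    means = prof.groupby("group")[
        ["prop_in_hours", "prop_contiguous", "prop_noncontiguous"]
    ].mean()
    fig, ax = plt.subplots(figsize=(6, 4))
    means.plot.bar(ax=ax)
    ax.set_ylabel("share of daily inbox time")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
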