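"""Shared fixtures: a reduced synthetic cohort and event-frame builders."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

from inboxstress import pipeline, synthetic_data as sd


def make_events(rows):
    """Event frame from (timestamp, category, message_type, window_id, task) tuples."""
    return pd.DataFrame(
        {
            "timestamp": pd.to_datetime([r[0] for r in rows]),
            "physician_id": [r[5] if len(r) > 5 else "P0" for r in rows],
            "category": [r[1] for r in rows],
            "message_type": [r[2] for r in rows],
            "window_id": [r[3] for r in rows],
            "is_task_completion": [r[4] for r in rows],
        }
    )


def inbox_event(ts, window="W1", task=False, pid="P0"):
    return (ts, "INBOX", "PATIENT", window, task, pid)


def other_event(ts, window="W1", pid="P0"):
    return (ts, "OTHER_EHR", "NONE", window, False, pid)


@pytest.fixture(scope="session")
def small_prototypes():
    return tuple(
        dataclasses.replace(p, n_physicians=n)
        for p, n in zip(sd.STUDY_PROTOTYPES, (4, 6, 6))
    )


@pytest.fixture(scope="session")
def small_cfg():
    return sd.CohortConfig(n_workdays=3, n_nonworkdays=1, n_device_failures=1)


@pytest.fixture(scope="session")
def small_cohort(small_cfg, small_prototypes):
    return sd.generate_cohort(small_cfg, small_prototypes, seed=42)


@pytest.fixture(scope="session")
def small_day_features(small_cohort):
    return pipeline.compute_day_features(small_cohort.events)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)
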