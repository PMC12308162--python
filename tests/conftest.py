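from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from engagelog import (GeneratorParams, ObservationWindow, default_content,
                       simulate_dataset)


def make_events(rows: list[tuple]) -> pd.DataFrame:
    """Build an event frame from (user_id, iso_time, page, feature, component,
    action, module) tuples."""
    df = pd.DataFrame(rows, columns=["user_id", "timestamp", "page_id", "feature_id",
                                     "component", "action", "module_id"])
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    return df


def make_cohort(user_ids: list[str], access_start: str = "2021-06-01", **overrides) -> pd.DataFrame:
    """Minimal valid cohort rows with constant defaults, overridable per column."""
    n = len(user_ids)
    base = {
        "user_id": user_ids,
        "parent_age": 34.0, "is_mother": 1.0, "australian_born": 1.0,
        "university_degree": 1.0, "work_hours": 20.0, "partner_cohabiting": 1.0,
        "siblings_in_family": 0.0, "remoteness": "major_city",
        "seifa_score": 1000.0, "coping": 3.0,
        "concern_sitting": 2.0, "concern_activity": 2.0,
        "concern_screen": 2.0, "concern_sleep": 2.0,
        "info_seek_activity": 1.0, "info_seek_screen": 0.5, "info_seek_sleep": 0.5,
        "child_female": 1.0, "child_temperament": "average",
        "access_start": pd.Timestamp(access_start, tz="UTC"),
        "lockdown_days": 10.0, "downtime_days": 2.0,
    }
    base.update(overrides)
    return pd.DataFrame({k: (v if isinstance(v, (list, np.ndarray, pd.Series))
                             else [v] * n) for k, v in base.items()})


@pytest.fixture(scope="session")
def content():
    return default_content()


@pytest.fixture(scope="session")
def small_simulation():
    """One modest synthetic dataset shared across tests (n=120, seed 42)."""
    params = GeneratorParams(n_enrollees=120)
    return simulate_dataset(params, seed=42)


@pytest.fixture(scope="session")
def default_simulation():
    """One full-size synthetic dataset under default study conditions."""
    return simulate_dataset(GeneratorParams(), seed=7)


@pytest.fixture()
def window_factory():
    def _make(cohort: pd.DataFrame, length_days: int = 175) -> ObservationWindow:
        return ObservationWindow.from_cohort(cohort, length_days=length_days)
    return _make
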