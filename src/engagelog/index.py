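"""Composite engagement index (EI): subindexes, normalization, weekly series.

The EI is an adaptation of a web-analytics visitor index to intervention
apps. Four per-user subindexes are computed from the raw event log:

* **click depth** — mean number of app pages viewed per active day;
* **loyalty** — number of distinct active days;
* **recency** — mean gap in days between consecutive active days (lower is
  better, so it is reversed before rescaling);
* **diversity** — mean number of distinct features used per active day.

Each subindex is rescaled to 0–100 so all four carry equal weight, and the
EI is their arithmetic mean. Because the rescaling rule is stated only as
"rescale between 0 and 100", two strategies are provided:

* ``cohort-minmax`` (default): min–max over the analysis cohort, with
  recency negated before rescaling. A subindex with zero range across the
  cohort maps everyone to 50 (no information, neutral score).
* ``theoretical-max``: loyalty and recency are scaled against the window
  length (their natural maxima); click depth and diversity, which have no
  theoretical ceiling, are scaled against the cohort maximum.

A weekly EI is computed the same way inside each 7-day user-clock slice,
normalized across that week's active users only; user-weeks without events
produce no record.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd

from .events import ObservationWindow
from .metrics import classify_user_status, users_of

SUBINDEXES = ["click_depth", "loyalty", "recency", "diversity"]
STRATEGIES = ("cohort-minmax", "theoretical-max")


def _raw_from_slice(ev: pd.DataFrame, worst_recency: float) -> pd.DataFrame:
    """Raw subindexes from an event slice that already has a ``day`` column.

    ``worst_recency`` is the value assigned when a user has a single active
    day in the slice (no gaps exist): the slice length in days, i.e. the
    worst possible spacing, so that one-shot visitors are not rewarded.
    """
    ud = (ev[["user_id", "day"]].drop_duplicates()
          .sort_values(["user_id", "day"], kind="stable"))
    ud["gap"] = ud.groupby("user_id")["day"].diff()
    loyalty = ud.groupby("user_id").size().astype(float)
    recency = ud.groupby("user_id")["gap"].mean().fillna(float(worst_recency))
    views = (ev[ev["action"] == "page_view"].groupby("user_id").size()
             .reindex(loyalty.index, fill_value=0))
    click_depth = views / loyalty
    per_day_feats = ev.groupby(["user_id", "day"])["feature_id"].nunique()
    diversity = per_day_feats.groupby(level=0).mean().reindex(loyalty.index, fill_value=0.0)
    out = pd.DataFrame({
        "click_depth_raw": click_depth.astype(float),
        "loyalty_raw": loyalty,
        "recency_raw": recency.astype(float),
        "diversity_raw": diversity.astype(float),
    })
    out.index.name = "user_id"
    return out


def raw_subindexes(events: pd.DataFrame, window: ObservationWindow) -> pd.DataFrame:
    """Per-user raw subindex values over the whole observation window.

    Users contributing zero windowed events are excluded with a warning
    (they have no active day to anchor any of the four quantities).
    """
    ev = window.clip(events)
    present = set(ev["user_id"])
    absent = sorted(set(events["user_id"]) - present)
    if absent:
        warnings.warn(
            f"{len(absent)} user(s) with no in-window events excluded from subindexes",
            stacklevel=2)
    if ev.empty:
        return pd.DataFrame(columns=[f"{s}_raw" for s in SUBINDEXES]).rename_axis("user_id")
    return _raw_from_slice(ev, worst_recency=window.length_days)


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = np.min(x), np.max(x)
    if hi == lo:
        return np.full(x.shape, 50.0)
    return (x - lo) / (hi - lo) * 100.0


def _ratio_to_max(x: np.ndarray) -> np.ndarray:
    hi = np.max(x)
    if hi == 0:
        return np.full(x.shape, 50.0)
    return np.clip(x / hi * 100.0, 0.0, 100.0)


def normalize_subindexes(raw: pd.DataFrame, strategy: str = "cohort-minmax",
                         window: Optional[ObservationWindow] = None,
                         length_days: Optional[int] = None) -> pd.DataFrame:
    """Rescale raw subindexes to 0-100.

    ``strategy='theoretical-max'`` needs the window length (pass ``window``
    or ``length_days``) to anchor loyalty and recency.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
    if raw.empty:
        return pd.DataFrame(columns=SUBINDEXES).rename_axis(raw.index.name)
    cd = raw["click_depth_raw"].to_numpy(float)
    lo = raw["loyalty_raw"].to_numpy(float)
    re = raw["recency_raw"].to_numpy(float)
    dv = raw["diversity_raw"].to_numpy(float)
    if strategy == "cohort-minmax":
        out = {
            "click_depth": _minmax(cd),
            "loyalty": _minmax(lo),
            "recency": _minmax(-re),  # reversed: larger gaps -> lower score
            "diversity": _minmax(dv),
        }
    else:
        L = length_days if length_days is not None else (
            window.length_days if window is not None else None)
        if L is None:
            raise ValueError("theoretical-max strategy needs window or length_days")
        out = {
            "click_depth": _ratio_to_max(cd),
            "loyalty": np.clip(lo / L * 100.0, 0.0, 100.0),
            "recency": np.clip((1.0 - (re - 1.0) / (L - 1.0)) * 100.0, 0.0, 100.0),
            "diversity": _ratio_to_max(dv),
        }
    return pd.DataFrame(out, index=raw.index)


def engagement_index(subindexes: pd.DataFrame) -> pd.DataFrame:
    """Fill the composite EI: the arithmetic mean of the four subindexes."""
    out = subindexes.copy()
    out["ei"] = out[SUBINDEXES].mean(axis=1)
    return out


def weekly_engagement_index(events: pd.DataFrame, window: ObservationWindow,
                            strategy: str = "cohort-minmax") -> pd.DataFrame:
    """Weekly EI for user-weeks with at least one event.

    Week ``w`` (1-based) covers user-clock days ``[7(w-1), 7w)``. Raw
    subindexes are computed inside each slice (single active day in a week
    gives the worst within-week recency, 7 days) and normalized across that
    week's active users only.
    """
    ev = window.clip(events)
    records = []
    if not ev.empty:
        week = ev["day"] // 7
        for w in range(window.n_weeks):
            sl = ev[week == w].copy()
            if sl.empty:
                continue
            sl["day"] = sl["day"] - 7 * w
            raw = _raw_from_slice(sl, worst_recency=7)
            norm = normalize_subindexes(raw, strategy=strategy, length_days=7)
            norm = engagement_index(norm)
            norm = norm.rename(columns={"ei": "ei_week"}).reset_index()
            norm.insert(1, "week", w + 1)
            records.append(norm)
    if not records:
        return pd.DataFrame(columns=["user_id", "week", *SUBINDEXES, "ei_week"])
    return pd.concat(records, ignore_index=True)


def access_trajectory(events: pd.DataFrame, cohort: pd.DataFrame,
                      window: ObservationWindow,
                      status: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Fraction of users with >= 1 event in each user-clock week.

    The denominator is the full user population (enrollees classified as
    users), not that week's actives, so the series traces retention.
    """
    if status is None:
        status = classify_user_status(events, cohort)
    users = users_of(status)
    n_users = len(users)
    ev = window.clip(events)
    ev = ev[ev["user_id"].isin(set(users))]
    weeks = np.arange(1, window.n_weeks + 1)
    if ev.empty or n_users == 0:
        return pd.DataFrame({"week": weeks, "n_active": 0,
                             "fraction": 0.0 if n_users else np.nan})
    wk = (ev["day"] // 7) + 1
    n_active = (ev.assign(week=wk).groupby("week")["user_id"].nunique()
                .reindex(weeks, fill_value=0))
    return pd.DataFrame({"week": weeks, "n_active": n_active.to_numpy(),
                         "fraction": n_active.to_numpy() / n_users})
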