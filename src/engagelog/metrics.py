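"""Individual engagement metrics and user/nonuser classification.

Given a windowed event log, this module computes the descriptive per-user
engagement measures of a digital-intervention study: total time in app
(via sessionization), distinct days of use, proportions of the app's pages
and features ever visited, click counts per component, modules completed and
forum actions. An enrollee counts as a *user* only if they logged in at
least once **and** produced at least one non-login event; everyone else is a
nonuser (never logged in, or never progressed past the login page).
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .events import AppContent, ObservationWindow

STATUS_USER = "user"
STATUS_NO_LOGIN = "nonuser_no_login"
STATUS_LOGIN_ONLY = "nonuser_login_only"

#: Columns of the per-user metrics table, mirroring the study's descriptive
#: engagement block (plus faq/system click counts so that component clicks
#: partition all non-login events).
METRIC_COLUMNS = [
    "total_minutes", "active_days", "prop_pages", "prop_features",
    "clicks_modules", "clicks_toolkit", "clicks_forum", "clicks_faq", "clicks_system",
    "modules_completed", "forum_posts", "forum_likes", "forum_comments",
    "ever_modules", "ever_toolkit", "ever_forum",
]


def classify_user_status(events: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """Partition every enrollee into user / nonuser_login_only / nonuser_no_login.

    ``user``: at least one login and at least one non-login page/feature event.
    ``nonuser_login_only``: login events only. ``nonuser_no_login``: no login
    at all (including enrollees with zero events).
    """
    is_login = events["action"] == "login"
    with_login = set(events.loc[is_login, "user_id"])
    with_use = set(events.loc[~is_login, "user_id"])
    uid = cohort["user_id"]
    login = uid.isin(with_login).to_numpy()
    use = uid.isin(with_use).to_numpy()
    status = np.where(login & use, STATUS_USER,
                      np.where(login, STATUS_LOGIN_ONLY, STATUS_NO_LOGIN))
    return pd.DataFrame({"user_id": uid.to_numpy(), "status": status})


def users_of(status: pd.DataFrame) -> list[str]:
    return status.loc[status["status"] == STATUS_USER, "user_id"].tolist()


def sessionize(events: pd.DataFrame, gap_threshold: float = 30.0,
               min_dwell: float = 1.0) -> pd.DataFrame:
    """Group events into sessions by an inactivity gap.

    Consecutive events of one user whose gap is <= ``gap_threshold`` minutes
    share a session; session duration (minutes) = span from first to last
    event + ``min_dwell``, so a single-event session lasts ``min_dwell``
    minutes. Returns one row per session: user_id, start, end,
    duration_minutes, n_events.
    """
    if gap_threshold < 0:
        raise ValueError("gap_threshold must be non-negative")
    if min_dwell < 0:
        raise ValueError("min_dwell must be non-negative")
    if events.empty:
        return pd.DataFrame(columns=["user_id", "start", "end", "duration_minutes", "n_events"])
    ev = events.sort_values(["user_id", "timestamp"], kind="stable")
    ts = pd.to_datetime(ev["timestamp"], utc=True)
    same_user = ev["user_id"].to_numpy() == np.roll(ev["user_id"].to_numpy(), 1)
    same_user[0] = False
    gap_min = ts.diff().dt.total_seconds().to_numpy() / 60.0
    new_session = ~same_user | (gap_min > gap_threshold)
    sid = np.cumsum(new_session)
    grp = pd.DataFrame({"user_id": ev["user_id"].to_numpy(), "ts": ts.to_numpy(), "sid": sid})
    agg = grp.groupby("sid").agg(
        user_id=("user_id", "first"), start=("ts", "first"),
        end=("ts", "last"), n_events=("ts", "size"))
    agg["duration_minutes"] = (
        (agg["end"] - agg["start"]).dt.total_seconds() / 60.0 + min_dwell
    )
    return agg[["user_id", "start", "end", "duration_minutes", "n_events"]].reset_index(drop=True)


def compute_individual_metrics(events: pd.DataFrame, content: AppContent,
                               window: ObservationWindow,
                               users: Optional[Iterable[str]] = None,
                               gap_threshold: float = 30.0,
                               min_dwell: float = 1.0) -> pd.DataFrame:
    """Per-user engagement metrics over the observation window.

    ``prop_pages`` / ``prop_features`` are percentages of the content's page
    and feature inventories visited at least once (identifiers absent from
    the content descriptor are excluded from numerators; the denominators are
    fixed by the descriptor). A "click" is any non-login event with a known
    component; a module counts as completed only when every one of its
    activities has a ``complete_activity`` event inside the window.

    If ``users`` is given, the result has exactly one row per listed user
    (all-zero rows for users without windowed events); otherwise one row per
    user present in the windowed events.
    """
    ev = window.clip(events)
    idx = pd.Index(sorted(set(users)) if users is not None
                   else sorted(set(ev["user_id"])), name="user_id")
    out = pd.DataFrame(0.0, index=idx, columns=METRIC_COLUMNS)
    if not ev.empty:
        ev = ev[ev["user_id"].isin(idx)]

    sess = sessionize(ev, gap_threshold=gap_threshold, min_dwell=min_dwell)
    if not sess.empty:
        out["total_minutes"] = sess.groupby("user_id")["duration_minutes"].sum().reindex(
            idx, fill_value=0.0)

    if not ev.empty:
        out["active_days"] = ev.groupby("user_id")["day"].nunique().reindex(idx, fill_value=0)

        pv = ev[ev["page_id"].isin(content.page_ids)]
        out["prop_pages"] = (
            pv.groupby("user_id")["page_id"].nunique().reindex(idx, fill_value=0)
            * 100.0 / max(len(content.pages), 1))
        fv = ev[ev["feature_id"].isin(content.feature_ids)]
        out["prop_features"] = (
            fv.groupby("user_id")["feature_id"].nunique().reindex(idx, fill_value=0)
            * 100.0 / max(len(content.features), 1))

        clicks = ev[(ev["action"] != "login") & ev["component"].isin(
            ["module", "toolkit", "forum", "faq", "system"])]
        by_comp = clicks.groupby(["user_id", "component"]).size().unstack(fill_value=0)
        for comp, col in [("module", "clicks_modules"), ("toolkit", "clicks_toolkit"),
                          ("forum", "clicks_forum"), ("faq", "clicks_faq"),
                          ("system", "clicks_system")]:
            if comp in by_comp.columns:
                out[col] = by_comp[comp].reindex(idx, fill_value=0)

        done = ev[ev["action"] == "complete_activity"]
        if not done.empty:
            acts_done = done.groupby("user_id")["feature_id"].agg(set)
            needed = [set(m.activities) for m in content.modules]
            out["modules_completed"] = acts_done.map(
                lambda s: sum(req <= s for req in needed)).reindex(idx, fill_value=0)

        forum = ev[ev["component"] == "forum"]
        for act, col in [("post", "forum_posts"), ("like", "forum_likes"),
                         ("comment", "forum_comments")]:
            out[col] = (forum[forum["action"] == act].groupby("user_id").size()
                        .reindex(idx, fill_value=0))

    out["ever_modules"] = out["clicks_modules"] > 0
    out["ever_toolkit"] = out["clicks_toolkit"] > 0
    out["ever_forum"] = out["clicks_forum"] > 0
    for c in ["active_days", "clicks_modules", "clicks_toolkit", "clicks_forum",
              "clicks_faq", "clicks_system", "modules_completed",
              "forum_posts", "forum_likes", "forum_comments"]:
        out[c] = out[c].astype(int)
    return out


def earliest_completion_week(content: AppContent) -> int:
    """Shortest possible number of weeks to finish every module.

    With one module open at a time and each needing its minimum duration
    before the next unlocks, the earliest full-program completion is simply
    the sum of the per-module minimum durations.
    """
    if not content.modules:
        raise ValueError("content has no modules")
    return int(sum(m.min_duration_weeks for m in content.modules))
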