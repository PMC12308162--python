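"""Independent brute-force reference implementations used only by tests.

Everything here is written against plain Python dict/list representations of
events, deliberately avoiding the pipeline's pandas code paths, so that a
match between the two is evidence rather than tautology.
"""

from __future__ import annotations

import math
from collections import defaultdict

import numpy as np
from scipy import stats


def events_as_dicts(events) -> list[dict]:
    recs = events.to_dict("records")
    for r in recs:
        r["timestamp"] = r["timestamp"].to_pydatetime()
    return recs


def naive_sessions(user_events: list[dict], gap_minutes: float, min_dwell: float) -> list[dict]:
    """Sessionize one user's time-sorted events by naive enumeration."""
    sessions = []
    current = None
    for ev in sorted(user_events, key=lambda e: e["timestamp"]):
        if current is None:
            current = [ev]
        else:
            gap = (ev["timestamp"] - current[-1]["timestamp"]).total_seconds() / 60.0
            if gap <= gap_minutes:
                current.append(ev)
            else:
                sessions.append(current)
                current = [ev]
    if current:
        sessions.append(current)
    return [
        {
            "start": s[0]["timestamp"],
            "end": s[-1]["timestamp"],
            "n_events": len(s),
            "duration_minutes":
                (s[-1]["timestamp"] - s[0]["timestamp"]).total_seconds() / 60.0 + min_dwell,
        }
        for s in sessions
    ]


def naive_metrics(events: list[dict], content, access_start: dict, window_days: int,
                  gap_minutes: float = 30.0, min_dwell: float = 1.0) -> dict:
    """Per-user recount of every individual metric, one event at a time."""
    by_user: dict[str, list[dict]] = defaultdict(list)
    for ev in events:
        uid = ev["user_id"]
        day = math.floor((ev["timestamp"] - access_start[uid]).total_seconds() / 86400.0)
        if 0 <= day < window_days:
            by_user[uid].append({**ev, "day": day})

    known_pages = set(content.pages)
    known_feats = set(content.features)
    out = {}
    for uid, evs in by_user.items():
        days = {e["day"] for e in evs}
        pages = {e["page_id"] for e in evs
                 if isinstance(e["page_id"], str) and e["page_id"] in known_pages}
        feats = {e["feature_id"] for e in evs
                 if isinstance(e["feature_id"], str) and e["feature_id"] in known_feats}
        clicks = defaultdict(int)
        for e in evs:
            if e["action"] != "login" and e["component"] in (
                    "module", "toolkit", "forum", "faq", "system"):
                clicks[e["component"]] += 1
        done = {e["feature_id"] for e in evs if e["action"] == "complete_activity"}
        n_done = sum(1 for m in content.modules if set(m.activities) <= done)
        forum_counts = {a: sum(1 for e in evs
                               if e["component"] == "forum" and e["action"] == a)
                        for a in ("post", "like", "comment")}
        out[uid] = {
            "total_minutes": sum(s["duration_minutes"]
                                 for s in naive_sessions(evs, gap_minutes, min_dwell)),
            "active_days": len(days),
            "prop_pages": 100.0 * len(pages) / len(content.pages),
            "prop_features": 100.0 * len(feats) / len(content.features),
            "clicks_modules": clicks["module"],
            "clicks_toolkit": clicks["toolkit"],
            "clicks_forum": clicks["forum"],
            "modules_completed": n_done,
            "forum_posts": forum_counts["post"],
            "forum_likes": forum_counts["like"],
            "forum_comments": forum_counts["comment"],
        }
    return out


def naive_raw_subindexes(events: list[dict], access_start: dict, window_days: int) -> dict:
    by_user: dict[str, list[dict]] = defaultdict(list)
    for ev in events:
        uid = ev["user_id"]
        day = math.floor((ev["timestamp"] - access_start[uid]).total_seconds() / 86400.0)
        if 0 <= day < window_days:
            by_user[uid].append({**ev, "day": day})
    out = {}
    for uid, evs in by_user.items():
        days = sorted({e["day"] for e in evs})
        loyalty = len(days)
        if loyalty >= 2:
            gaps = [b - a for a, b in zip(days, days[1:])]
            recency = sum(gaps) / len(gaps)
        else:
            recency = float(window_days)
        views = sum(1 for e in evs if e["action"] == "page_view")
        per_day = []
        for d in days:
            per_day.append(len({e["feature_id"] for e in evs
                                if e["day"] == d and isinstance(e["feature_id"], str)}))
        out[uid] = {
            "click_depth_raw": views / loyalty,
            "loyalty_raw": float(loyalty),
            "recency_raw": float(recency),
            "diversity_raw": sum(per_day) / len(per_day),
        }
    return out


def ols_normal_equations(x: np.ndarray, y: np.ndarray,
                         extra: np.ndarray | None = None) -> dict:
    """Least squares via the normal equations, with residual-t intervals."""
    X = np.column_stack([np.ones_like(x), x] if extra is None
                        else [np.ones_like(x), x, extra])
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.inv(XtX)
    se = math.sqrt(cov[1, 1])
    tcrit = stats.t.ppf(0.975, df)
    tstat = beta[1] / se if se > 0 else math.inf * np.sign(beta[1])
    p = 2 * stats.t.sf(abs(tstat), df)
    return {"beta": float(beta[1]), "ci_low": float(beta[1] - tcrit * se),
            "ci_high": float(beta[1] + tcrit * se), "p_value": float(p)}


def chi_square_by_hand(table: np.ndarray) -> float:
    """Pearson chi-square statistic, sum over cells of (O - E)^2 / E."""
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    return float(((table - expected) ** 2 / expected).sum())
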