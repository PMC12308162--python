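"""Domain types and I/O for app event logs, cohort tables and app-content descriptors.

The atomic unit of the whole pipeline is a timestamped *app event*: one user
action in a progressive web app (a login, a page view, a click on a feature,
completion of a learning-module activity, or a forum post/like/comment).
Events live in a pandas DataFrame with the columns of :data:`EVENT_COLUMNS`:

``user_id``
    participant identifier (string, required).
``timestamp``
    ISO-8601 date-time; parsed to timezone-aware UTC at second resolution.
``page_id`` / ``feature_id``
    identifiers of the page viewed / feature used, empty when not applicable.
``component``
    one of ``module``, ``toolkit``, ``forum``, ``faq``, ``login``, ``system``.
``action``
    one of ``login``, ``page_view``, ``click``, ``complete_activity``,
    ``post``, ``like``, ``comment``.
``module_id``
    learning-module identifier; required when ``component == "module"``.

The cohort table has one row per enrollee with demographics, parental
characteristics, the date the participant was given app access
(``access_start``), and two context covariates (days spent in COVID-19
lockdown and days of app downtime experienced). Missing survey answers are
empty cells and stay missing (complete-case handling happens downstream).

All day-based quantities downstream use the *user clock*: day ``d`` is the
half-open 24-hour interval ``[access_start + d days, access_start + d+1 days)``
of that participant's own calendar, so staggered recruitment never mixes
calendar time across participants.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

COMPONENTS = ("module", "toolkit", "forum", "faq", "login", "system")
ACTIONS = ("login", "page_view", "click", "complete_activity", "post", "like", "comment")
FORUM_ACTIONS = frozenset({"post", "like", "comment"})

EVENT_COLUMNS = ["user_id", "timestamp", "page_id", "feature_id", "component", "action", "module_id"]

#: Documented cohort-table columns (header row of the delimited file).
COHORT_COLUMNS = [
    "user_id", "parent_age", "is_mother", "australian_born", "university_degree",
    "work_hours", "partner_cohabiting", "siblings_in_family", "remoteness",
    "seifa_score", "coping",
    "concern_sitting", "concern_activity", "concern_screen", "concern_sleep",
    "info_seek_activity", "info_seek_screen", "info_seek_sleep",
    "child_female", "child_temperament", "access_start",
    "lockdown_days", "downtime_days",
]

CONCERN_ITEMS = ["concern_sitting", "concern_activity", "concern_screen", "concern_sleep"]
INFO_SEEK_ITEMS = ["info_seek_activity", "info_seek_screen", "info_seek_sleep"]

REMOTENESS_LEVELS = ("major_city", "inner_regional", "outer_regional_remote")
TEMPERAMENT_LEVELS = ("easier", "average", "more_difficult")

_BOOL_COHORT_COLUMNS = [
    "is_mother", "australian_born", "university_degree", "partner_cohabiting",
    "siblings_in_family", "child_female",
]


class ModuleDescriptor(BaseModel):
    """One self-paced learning module: its pages, activity features and the
    minimum elapsed time (weeks) needed to complete it before the next module
    unlocks."""

    module_id: str
    activities: list[str]
    pages: list[str] = Field(default_factory=list)
    min_duration_weeks: int = Field(ge=2, le=5)


class AppContent(BaseModel):
    """Descriptor of everything the app contains.

    ``pages`` and ``features`` map each identifier to the component it belongs
    to, so every feature belongs to exactly one component by construction.
    ``modules`` is the ordered list of learning modules.
    """

    pages: dict[str, str]
    features: dict[str, str]
    modules: list[ModuleDescriptor]

    @field_validator("pages", "features")
    @classmethod
    def _known_components(cls, v: dict[str, str]) -> dict[str, str]:
        bad = {c for c in v.values() if c not in COMPONENTS}
        if bad:
            raise ValueError(f"unknown component(s): {sorted(bad)}")
        return v

    @model_validator(mode="after")
    def _activities_are_features(self) -> "AppContent":
        for m in self.modules:
            for a in m.activities:
                if self.features.get(a) != "module":
                    raise ValueError(
                        f"activity {a!r} of module {m.module_id!r} is not a module feature"
                    )
        return self

    @property
    def page_ids(self) -> set[str]:
        return set(self.pages)

    @property
    def feature_ids(self) -> set[str]:
        return set(self.features)

    @property
    def module_ids(self) -> list[str]:
        return [m.module_id for m in self.modules]

    def activities_of(self, module_id: str) -> list[str]:
        for m in self.modules:
            if m.module_id == module_id:
                return list(m.activities)
        raise KeyError(module_id)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AppContent":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))


def default_content() -> AppContent:
    """Default app-content fixture.

    Eight learning modules whose minimum durations (weeks) are
    ``3,3,3,3,3,3,2,2`` — each within the allowed 2–5 week band and summing to
    22, the shortest possible time to work through the full program under
    sequential unlock. Each module carries 12 pages and 4 activity features
    (most of the app's content sits inside modules and stays locked until
    reached, which keeps the fraction of pages a typical user ever sees low);
    the always-available components contribute a 20-page/8-feature toolkit,
    a small forum and an FAQ section.
    """
    durations = [3, 3, 3, 3, 3, 3, 2, 2]
    pages: dict[str, str] = {}
    features: dict[str, str] = {}
    modules: list[ModuleDescriptor] = []
    for i, dur in enumerate(durations, start=1):
        mid = f"mod{i}"
        mpages = [f"{mid}_p{j}" for j in range(1, 13)]
        macts = [f"{mid}_act{j}" for j in range(1, 5)]
        pages.update({p: "module" for p in mpages})
        features.update({a: "module" for a in macts})
        modules.append(
            ModuleDescriptor(module_id=mid, activities=macts, pages=mpages,
                             min_duration_weeks=dur)
        )
    pages.update({f"toolkit_p{j}": "toolkit" for j in range(1, 21)})
    features.update({f"toolkit_f{j}": "toolkit" for j in range(1, 9)})
    pages.update({f"forum_p{j}": "forum" for j in range(1, 5)})
    features.update({f"forum_f{j}": "forum" for j in range(1, 4)})
    pages.update({f"faq_p{j}": "faq" for j in range(1, 4)})
    features.update({f"faq_f{j}": "faq" for j in range(1, 3)})
    return AppContent(pages=pages, features=features, modules=modules)


@dataclasses.dataclass(frozen=True)
class ObservationWindow:
    """Per-user observation window.

    ``origin`` maps each user to their own ``access_start``; the window covers
    user-clock days ``[0, length_days)``. The default 175 days = 25 weeks.
    """

    origin: pd.Series  # user_id -> Timestamp (UTC)
    length_days: int = 175

    def __post_init__(self) -> None:
        if self.length_days % 7 != 0:
            raise ValueError("length_days must be divisible by 7 for weekly indexing")
        if self.length_days <= 0:
            raise ValueError("length_days must be positive")

    @property
    def n_weeks(self) -> int:
        return self.length_days // 7

    @classmethod
    def from_cohort(cls, cohort: pd.DataFrame, length_days: int = 175) -> "ObservationWindow":
        origin = pd.Series(
            pd.to_datetime(cohort["access_start"].to_numpy(), utc=True),
            index=cohort["user_id"].to_numpy(),
        )
        return cls(origin=origin, length_days=length_days)

    def user_days(self, events: pd.DataFrame) -> pd.Series:
        """User-clock day index of each event: floor(elapsed / 24 h)."""
        origin = pd.Series(
            pd.DatetimeIndex(self.origin).tz_convert("UTC").tz_localize(None).to_numpy(),
            index=self.origin.index)
        starts = origin.reindex(events["user_id"].to_numpy()).to_numpy()
        ts = (pd.DatetimeIndex(events["timestamp"]).tz_convert("UTC")
              .tz_localize(None).to_numpy())
        days = np.floor((ts - starts) / np.timedelta64(1, "D"))
        return pd.Series(days, index=events.index, dtype=float)

    def clip(self, events: pd.DataFrame) -> pd.DataFrame:
        """Restrict events to the window; adds a ``day`` column (int)."""
        day = self.user_days(events)
        keep = (day >= 0) & (day < self.length_days) & day.notna()
        out = events.loc[keep].copy()
        out["day"] = day.loc[keep].astype(int)
        return out


@dataclasses.dataclass
class ValidationIssue:
    kind: str
    line: Optional[int] = None
    user_id: Optional[str] = None
    detail: str = ""


@dataclasses.dataclass
class EventLog:
    """An event table plus the non-fatal issues found while reading it."""

    events: pd.DataFrame
    flags: list[ValidationIssue] = dataclasses.field(default_factory=list)

    def __len__(self) -> int:
        return len(self.events)


def _empty_to_nan(s: pd.Series) -> pd.Series:
    return s.mask(s.isin(["", "None"]) | s.isna(), np.nan)


def read_event_log(path: str | Path, content: Optional[AppContent] = None) -> EventLog:
    """Read an event log from delimited text (CSV) or JSON-lines.

    Events come back sorted by ``(user_id, timestamp)`` with ties broken by
    on-disk order. Rows with unparseable timestamps are flagged with their
    line number and excluded from the table; unknown page/feature identifiers
    (relative to ``content``) are flagged but kept. A missing ``user_id``
    is a hard failure.
    """
    path = Path(path)
    jsonl = path.suffix in {".jsonl", ".ndjson"}
    if jsonl:
        df = pd.read_json(path, lines=True, dtype=str)
        header_offset = 1  # first data row is file line 1
    else:
        df = pd.read_csv(path, dtype=str)
        header_offset = 2  # header is line 1
    missing_cols = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"event log missing column(s): {missing_cols}")
    df = df[EVENT_COLUMNS].copy()
    for c in EVENT_COLUMNS:
        df[c] = _empty_to_nan(df[c].astype("string").astype(object))

    if df["user_id"].isna().any():
        bad = [int(i) + header_offset for i in df.index[df["user_id"].isna()]]
        raise ValueError(f"missing user_id on line(s) {bad[:10]}")

    flags: list[ValidationIssue] = []
    ts = pd.to_datetime(df["timestamp"], errors="coerce", utc=True)
    for i in df.index[ts.isna()]:
        flags.append(ValidationIssue(
            kind="bad_timestamp", line=int(i) + header_offset,
            user_id=df.at[i, "user_id"],
            detail=f"unparseable timestamp {df.at[i, 'timestamp']!r}",
        ))
    df["timestamp"] = ts.dt.floor("s")
    df = df.loc[ts.notna()]

    for i in df.index:
        comp, act = df.at[i, "component"], df.at[i, "action"]
        if isinstance(comp, str) and comp not in COMPONENTS:
            flags.append(ValidationIssue("unknown_component", int(i) + header_offset,
                                         df.at[i, "user_id"], f"component {comp!r}"))
        if isinstance(act, str) and act not in ACTIONS:
            flags.append(ValidationIssue("unknown_action", int(i) + header_offset,
                                         df.at[i, "user_id"], f"action {act!r}"))
    if content is not None:
        known_pages, known_feats = content.page_ids, content.feature_ids
        for i in df.index:
            p, f = df.at[i, "page_id"], df.at[i, "feature_id"]
            if isinstance(p, str) and p not in known_pages:
                flags.append(ValidationIssue("unknown_page", int(i) + header_offset,
                                             df.at[i, "user_id"], f"page_id {p!r}"))
            if isinstance(f, str) and f not in known_feats:
                flags.append(ValidationIssue("unknown_feature", int(i) + header_offset,
                                             df.at[i, "user_id"], f"feature_id {f!r}"))

    df = df.sort_values(["user_id", "timestamp"], kind="stable").reset_index(drop=True)
    return EventLog(events=df, flags=flags)


def write_event_log(events: pd.DataFrame, path: str | Path) -> None:
    """Write events to CSV or JSON-lines (by extension) with ISO timestamps."""
    path = Path(path)
    out = events[EVENT_COLUMNS].copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True).dt.strftime(
        "%Y-%m-%dT%H:%M:%S%z"
    )
    if path.suffix in {".jsonl", ".ndjson"}:
        out.to_json(path, orient="records", lines=True)
    else:
        out.to_csv(path, index=False)


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    """Read the cohort table (delimited text, one row per enrollee).

    Missing cells are preserved as NaN. A duplicated ``user_id`` or a
    non-missing coping score outside [1, 5] is a hard failure.
    """
    df = pd.read_csv(path, dtype=str)
    missing_cols = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"cohort table missing column(s): {missing_cols}")
    df = df[COHORT_COLUMNS].copy()
    for c in COHORT_COLUMNS:
        df[c] = _empty_to_nan(df[c].astype("string").astype(object))

    if df["user_id"].isna().any():
        raise ValueError("cohort table has rows with missing user_id")
    dup = df["user_id"][df["user_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate user_id(s): {sorted(set(dup))[:10]}")

    bool_map = {"1": 1.0, "0": 0.0, "true": 1.0, "false": 0.0, "yes": 1.0, "no": 0.0,
                "1.0": 1.0, "0.0": 0.0}
    for c in _BOOL_COHORT_COLUMNS:
        df[c] = df[c].map(lambda v: bool_map.get(str(v).strip().lower(), np.nan)
                          if pd.notna(v) else np.nan)

    numeric = ["parent_age", "work_hours", "seifa_score", "coping",
               *CONCERN_ITEMS, *INFO_SEEK_ITEMS, "lockdown_days", "downtime_days"]
    for c in numeric:
        df[c] = pd.to_numeric(df[c], errors="coerce")

    coping = df["coping"].dropna()
    if ((coping < 1) | (coping > 5)).any():
        raise ValueError("coping score outside [1, 5]")
    wh = df["work_hours"].dropna()
    if (wh < 0).any():
        raise ValueError("negative work_hours")
    for c in ("remoteness",):
        bad = set(df[c].dropna()) - set(REMOTENESS_LEVELS)
        if bad:
            raise ValueError(f"unknown remoteness level(s): {sorted(bad)}")

    df["access_start"] = pd.to_datetime(df["access_start"], utc=True, errors="raise")
    return df.reset_index(drop=True)


def write_cohort_table(cohort: pd.DataFrame, path: str | Path) -> None:
    out = cohort[COHORT_COLUMNS].copy()
    out["access_start"] = pd.to_datetime(out["access_start"], utc=True).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


@dataclasses.dataclass
class ValidationReport:
    """Consistency report of an event log against content and cohort.

    ``unknown_users`` — user_ids in the log absent from the cohort table;
    ``sequencing`` — module events that touch a module not yet unlocked given
    the user's completion history (the app allows one open module at a time);
    ``out_of_window`` — events before access_start or at/after window end.
    Reporting only: nothing is dropped here.
    """

    unknown_users: list[str] = dataclasses.field(default_factory=list)
    sequencing: list[ValidationIssue] = dataclasses.field(default_factory=list)
    out_of_window: list[ValidationIssue] = dataclasses.field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (self.unknown_users or self.sequencing or self.out_of_window)


def validate_events(events: pd.DataFrame, content: AppContent,
                    cohort: pd.DataFrame,
                    window_days: int = 175) -> ValidationReport:
    """Check an event log against the sequential-unlock rule and the window.

    A module event is valid if its module is already completed (completed
    modules stay accessible), is the user's currently open module, or opens a
    new module while none is open. Any other module event is a sequencing
    violation. Completion state advances when ``complete_activity`` events
    cover a module's full activity list.
    """
    report = ValidationReport()
    known = set(cohort["user_id"])
    in_cohort = events["user_id"].isin(known)
    report.unknown_users = sorted(set(events.loc[~in_cohort, "user_id"]))

    ev = events.loc[in_cohort]
    window = ObservationWindow.from_cohort(cohort, length_days=window_days)
    day = window.user_days(ev)
    for i in ev.index[(day < 0) | (day >= window_days)]:
        report.out_of_window.append(ValidationIssue(
            kind="out_of_window", user_id=ev.at[i, "user_id"],
            detail=f"user-clock day {int(day.at[i])}"))

    activities = {m.module_id: set(m.activities) for m in content.modules}
    mod_ev = ev.loc[ev["component"] == "module"].sort_values(
        ["user_id", "timestamp"], kind="stable")
    for uid, grp in mod_ev.groupby("user_id", sort=False):
        completed: set[str] = set()
        open_mod: Optional[str] = None
        remaining: set[str] = set()
        for i in grp.index:
            m = grp.at[i, "module_id"]
            if not isinstance(m, str):
                report.sequencing.append(ValidationIssue(
                    kind="missing_module_id", user_id=uid,
                    detail="module event without module_id"))
                continue
            if m in completed:
                continue
            if open_mod is None:
                open_mod = m
                remaining = set(activities.get(m, set()))
            elif m != open_mod:
                report.sequencing.append(ValidationIssue(
                    kind="locked_module", user_id=uid,
                    detail=f"event in locked module {m!r} while {open_mod!r} is open"))
                continue
            if grp.at[i, "action"] == "complete_activity":
                remaining.discard(grp.at[i, "feature_id"])
                if not remaining:
                    completed.add(open_mod)
                    open_mod = None
    return report
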