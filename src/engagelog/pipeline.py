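"""End-to-end orchestration: config, full pipeline run, report bundle.

A :class:`PipelineConfig` either points at input files (event log, cohort
table, content descriptor) or carries a simulate block (generator
parameters) — exactly one of the two. :func:`run_pipeline` then executes
reading/simulation -> status classification -> individual metrics ->
subindexes/EI -> weekly EI and access trajectory -> association screening
and baseline comparisons, and returns every table in a
:class:`ReportBundle` together with a manifest (config hash, seed, library
versions) sufficient to regenerate the bundle bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .associations import (compare_users_nonusers, derive_covariates,
                           sensitivity_regressions, univariable_regressions)
from .events import (AppContent, ObservationWindow, default_content,
                     read_cohort_table, read_event_log, write_cohort_table,
                     write_event_log)
from .index import (access_trajectory, engagement_index, normalize_subindexes,
                    raw_subindexes, weekly_engagement_index)
from .metrics import classify_user_status, compute_individual_metrics, users_of
from .simulate import GeneratorParams, generate_cohort, generate_event_log, planted_truth

logger = logging.getLogger("engagelog")

#: Outcome columns carried into the association screening: the individual
#: metrics block plus the composite EI block.
OUTCOME_METRICS = ["total_minutes", "active_days", "prop_pages", "prop_features",
                   "clicks_modules", "clicks_toolkit", "clicks_forum"]
OUTCOME_COMPOSITE = ["ei", "click_depth", "loyalty", "recency", "diversity"]


class PipelineConfig(BaseModel):
    events_path: Optional[str] = None
    cohort_path: Optional[str] = None
    content_path: Optional[str] = None
    simulate: Optional[GeneratorParams] = None
    window_days: int = 175
    gap_threshold: float = 30.0
    min_dwell: float = 1.0
    strategy: str = "cohort-minmax"
    sensitivity: bool = True
    seed: int = 0
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _one_source(self) -> "PipelineConfig":
        paths = self.events_path is not None and self.cohort_path is not None
        if paths == (self.simulate is not None):
            raise ValueError(
                "config must provide exactly one of: (events_path and cohort_path) "
                "or a simulate block")
        return self

    def canonical_json(self) -> str:
        return json.dumps(json.loads(self.model_dump_json()), sort_keys=True)


@dataclasses.dataclass
class ReportBundle:
    """All pipeline outputs plus a reproducibility manifest."""

    cohort: pd.DataFrame
    content: AppContent
    status: pd.DataFrame
    metrics: pd.DataFrame
    subindexes: pd.DataFrame
    weekly_ei: pd.DataFrame
    trajectory: pd.DataFrame
    associations: pd.DataFrame
    comparisons: pd.DataFrame
    manifest: dict
    events: Optional[pd.DataFrame] = None
    effects: Optional[pd.DataFrame] = None

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_cohort_table(self.cohort, out / "cohort.csv")
        self.content.to_yaml(out / "content.yaml")
        self.status.to_csv(out / "status.csv", index=False)
        self.metrics.to_csv(out / "metrics.csv")
        self.subindexes.to_csv(out / "subindexes.csv")
        self.weekly_ei.to_csv(out / "weekly_ei.csv", index=False)
        self.trajectory.to_csv(out / "access_trajectory.csv", index=False)
        self.associations.to_csv(out / "associations.csv", index=False)
        self.comparisons.to_csv(out / "comparisons.csv", index=False)
        if self.events is not None:
            write_event_log(self.events, out / "events.csv")
        if self.effects is not None:
            self.effects.to_csv(out / "planted_effects.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2))


def _manifest(config: PipelineConfig) -> dict:
    import scipy
    import statsmodels

    return {
        "config": json.loads(config.model_dump_json()),
        "config_sha256": hashlib.sha256(config.canonical_json().encode()).hexdigest(),
        "seed": config.seed,
        "versions": {
            "engagelog": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "statsmodels": statsmodels.__version__,
        },
    }


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the whole analysis for one config; deterministic per seed."""
    logging.basicConfig(level=config.log_level)
    effects = None
    events_out = None
    if config.simulate is not None:
        logger.info("stage=simulate seed=%d n=%d", config.seed,
                    config.simulate.n_enrollees)
        content = (AppContent.from_yaml(config.content_path)
                   if config.content_path else default_content())
        cohort = generate_cohort(config.simulate, config.seed)
        events = generate_event_log(cohort, content, config.simulate, config.seed)
        effects = planted_truth(config.simulate)
        events_out = events
    else:
        logger.info("stage=read events=%s cohort=%s", config.events_path,
                    config.cohort_path)
        content = (AppContent.from_yaml(config.content_path)
                   if config.content_path else default_content())
        cohort = read_cohort_table(config.cohort_path)
        log = read_event_log(config.events_path, content)
        if log.flags:
            logger.warning("stage=read %d validation flag(s)", len(log.flags))
        events = log.events

    window = ObservationWindow.from_cohort(cohort, length_days=config.window_days)
    status = classify_user_status(events, cohort)
    users = users_of(status)
    logger.info("stage=classify users=%d/%d", len(users), len(cohort))
    user_events = events[events["user_id"].isin(set(users))]

    metrics = compute_individual_metrics(
        user_events, content, window, users=users,
        gap_threshold=config.gap_threshold, min_dwell=config.min_dwell)
    raw = raw_subindexes(user_events, window)
    sub = engagement_index(normalize_subindexes(raw, strategy=config.strategy,
                                                window=window))
    subindexes = raw.join(sub)
    weekly = weekly_engagement_index(user_events, window, strategy=config.strategy)
    trajectory = access_trajectory(events, cohort, window, status=status)

    predictors = derive_covariates(cohort)
    pred_users = predictors.loc[predictors.index.isin(users)]
    outcomes = metrics[OUTCOME_METRICS].join(sub[OUTCOME_COMPOSITE])
    assoc = univariable_regressions(pred_users, outcomes)
    if config.sensitivity:
        assoc = pd.concat(
            [assoc, sensitivity_regressions(pred_users, outcomes, cohort)],
            ignore_index=True)
    comparisons = compare_users_nonusers(predictors, status)
    logger.info("stage=associate records=%d", len(assoc))

    return ReportBundle(
        cohort=cohort, content=content, status=status, metrics=metrics,
        subindexes=subindexes, weekly_ei=weekly, trajectory=trajectory,
        associations=assoc, comparisons=comparisons, manifest=_manifest(config),
        events=events_out, effects=effects)


def plot_weekly_series(trajectory: pd.DataFrame, weekly_ei: pd.DataFrame, path: str | Path) -> None:
    """Optional helper: render the weekly access/EI curves to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mean_ei = weekly_ei.groupby("week")["ei_week"].mean()
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(trajectory["week"], trajectory["fraction"] * 100, label="accessing the app (%)")
    ax.plot(mean_ei.index, mean_ei.to_numpy(), label="mean weekly EI (%)")
    ax.set_xlabel("week of app access")
    ax.set_ylabel("percent")
    ax.set_ylim(0, 100)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
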