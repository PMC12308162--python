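# engagelog

Engagement analytics for module-based mHealth intervention apps.

Digital parenting and health-behaviour interventions delivered through apps
log every user action, but turning those raw event streams into defensible
engagement measures — and finding out *who* engages — requires a surprising
amount of machinery: per-user observation windows under staggered
recruitment, sessionization, user/nonuser classification, composite scoring
and predictor screening. `engagelog` packages that machinery for
biostatisticians and intervention researchers, together with a calibrated
synthetic cohort simulator so every step can be validated without access to
participant data.

## What it computes

From an event log (one row per user action: login, page view, click,
module-activity completion, forum post/like/comment) and a cohort table:

* **User status** — an enrollee is a *user* iff they logged in at least once
  and used at least one app feature; nonusers split into never-logged-in and
  login-only.
* **Individual metrics** — total minutes in app (30-min session gap, 1-min
  minimum dwell), distinct days of use, % of pages and features ever
  visited, clicks per component, modules completed, forum actions.
* **Engagement index (EI)** — the mean of four subindexes, each rescaled to
  0–100:

  * click depth — mean page views per active day
  * loyalty — number of active days
  * recency — mean gap (days) between active days, reversed
  * diversity — mean distinct features used per active day

  plus a weekly EI computed inside each 7-day slice and a weekly
  access-fraction trajectory.
* **Predictor screening** — one simple linear regression per
  predictor×outcome (11 baseline predictors × 12 engagement outcomes),
  complete-case per model, with 95% CIs and raw p-values; sensitivity
  variants adjust for lockdown days or app downtime; chi-square/t-test
  baseline comparisons of users vs nonusers.

The synthetic generator plants a known effect vector on a latent engagement
propensity and is calibrated so that, at its default study conditions (682
enrollees, 25 weeks), ~89.3% of enrollees become users and weekly access
declines from ~90.6% (week 1) to ~31.2% (week 25).

## Worked example

```python
from engagelog import GeneratorParams, PipelineConfig, run_pipeline

config = PipelineConfig(simulate=GeneratorParams(), seed=1)
bundle = run_pipeline(config)

print((bundle.status["status"] == "user").sum(), "users of", len(bundle.cohort))
print(bundle.metrics[["total_minutes", "active_days", "clicks_modules"]].mean())
print(bundle.trajectory[["week", "fraction"]].iloc[[0, 24]])
a = bundle.associations.query(
    "model == 'unadjusted' and outcome == 'ei' and predictor == 'university_degree'")
print(a[["beta", "ci_low", "ci_high", "p_value", "n_used"]])
```

prints (seed 1):

```
609 users of 682
total_minutes     65.4
active_days       20.0
clicks_modules    77.7
    week  fraction
0      1     0.887
24    25     0.307
    beta  ci_low  ci_high  p_value  n_used
    3.44    1.28     5.60   0.0018     609
```

Read: 609 of 682 simulated enrollees logged in and used at least one
feature; users averaged 65 minutes in the app over 20 active days; weekly
access fell from 88.7% to 30.7% across the 25 weeks; and holding a
university degree was associated with a 3.4-point higher engagement index
(95% CI 1.3–5.6) — the generator plants exactly this kind of positive
education effect, and the screening recovers it.

The same pipeline runs on real files by giving paths instead of a simulate
block (`events_path=`, `cohort_path=`, `content_path=`), or from the shell:

```bash
engagelog simulate --out-dir data --seed 1
engagelog metrics --events data/events.csv --cohort data/cohort.csv --out metrics.csv
engagelog index --events data/events.csv --cohort data/cohort.csv \
    --out ei.csv --weekly weekly_ei.csv --trajectory access.csv
engagelog run --config config.yaml --out-dir report
```

## Layout

```
src/engagelog/
  events.py        event/cohort/content types, readers, writers, validation
  simulate.py      synthetic cohort + event-log generator, planted effects
  metrics.py       sessionization, user status, individual metrics
  index.py         subindexes, EI, weekly EI, access trajectory
  associations.py  covariate derivation, regression screening, comparisons
  pipeline.py      config, end-to-end orchestration, report bundle
  cli.py           typer CLI (simulate / metrics / index / associate / run)
docs/methods.md    model assumptions, parameter choices, limitations
tests/             pytest suite incl. brute-force oracles and acceptance checks
```
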