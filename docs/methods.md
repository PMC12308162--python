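# Methods

## Scope and model

`engagelog` analyses participant engagement with a module-based mHealth
intervention app from its raw event log. The analysis chain is:

1. **Windowing.** Every enrollee has their own observation window of
   `window_days` (default 175 = 25 weeks) starting at their `access_start`.
   All day- and week-based quantities use this *user clock*: day *d* is the
   half-open interval `[access_start + d·24 h, access_start + (d+1)·24 h)`,
   week *w* (1-based) covers days `[7(w−1), 7w)`. Staggered recruitment makes
   per-user clocks the only consistent time frame; events outside the window
   are excluded from metrics but reported by the validator.

2. **User classification.** An enrollee is a *user* iff they logged in at
   least once **and** produced at least one non-login event. The remaining
   enrollees split into never-logged-in and login-only nonusers. All
   engagement metrics are computed for users only; nonusers enter the
   baseline-comparison tables.

3. **Individual metrics.** Total minutes in app (from sessionization),
   distinct active days, % of the app's pages and features ever visited
   (denominators fixed by the content descriptor), click counts per component
   (any non-login event with a known component; page views count as clicks),
   modules completed (a module counts only when its full activity set has
   `complete_activity` events inside the window) and forum
   posts/likes/comments.

4. **Composite engagement index.** Four per-user subindexes —
   click depth (page views per active day), loyalty (active days), recency
   (mean gap between consecutive active days; reversed), diversity (distinct
   features per active day) — each rescaled to 0–100 and averaged into the
   EI. A weekly EI repeats the construction inside each 7-day slice,
   normalized across that week's active users only.

5. **Association screening.** Each predictor×outcome pair gets its own
   simple linear regression (one predictor per model; the analysis never fits
   a joint multivariable model), complete-case per model, with residual-*t*
   95% CIs and two-sided p-values. Sensitivity variants add days-in-lockdown
   or app-downtime days as a covariate (separately by default; a joint
   variant is available). Raw p-values are reported; Benjamini–Hochberg is an
   opt-in extra column, never applied by default.

## Sessionization

Events of one user belong to the same session while consecutive gaps are
≤ `gap_threshold` minutes (default 30, the common web-analytics convention);
session duration is last-minus-first event time plus `min_dwell` minutes
(default 1), so a single-event session lasts `min_dwell`. Total time in app
is the sum of session durations and is therefore sensitive to both knobs;
they are plain parameters of every entry point and recorded in the run
manifest. Whether the original analytics backend applied a dwell correction
is unknowable from outside, which is exactly why this is configuration
rather than a hard-coded convention.

## Normalization strategies

The rescaling rule behind the EI is stated in the literature only as
"rescale between 0 % and 100 %", so two defensible readings are implemented
and labelled:

* `cohort-minmax` (default) — per-subindex min–max over the analysis cohort;
  recency is negated before rescaling so larger gaps score lower. A subindex
  with zero range maps everyone to 50 (no information → neutral score).
  Consequences worth knowing: scores are relative to the cohort, exactly one
  user attains 100 and one attains 0 per subindex (absent ties), and the
  cohort EI mean is *not* comparable across datasets with different raw
  distributions.
* `theoretical-max` — loyalty scaled by the window length, recency mapped by
  `100·(1 − (r−1)/(L−1))`; click depth and diversity, which have no natural
  ceiling, are scaled against the cohort maximum. Scores under this strategy
  are closer to absolute rates.

Single-active-day users get `recency_raw = window length` (7 within a weekly
slice): they have no observed gap, and treating them as missing would delete
the least-engaged users and bias the EI upward. Weekly normalization uses
only that week's active users, since the weekly EI is defined only for
participants with data in that week.

## Synthetic generator

The generator emulates the cohort and usage structure the analysis assumes,
with known ground truth, so recovery and calibration are testable. What it
emulates (defaults in parentheses):

* **Covariate marginals** — university 0.718, mother 0.982, Australian-born
  0.767, working 0.649 (hours ~ N(30, 10) clipped 4–50 among workers),
  partner 0.924, siblings 0.588, major city 0.718 / inner regional 0.192,
  age ~ N(34.9, 4.5) clipped 21–48, coping ~ N(3.2, 0.7) clipped [1, 5],
  four 5-point concern items from a Gaussian copula with shared-factor
  correlation 0.3 (sum ≈ 7.3, SD ≈ 2.9), information seeking as a 45 % point
  mass at zero plus a Gamma(0.5, 8) tail clipped to [0, 40] (mean ≈ 2.2,
  SD ≈ 4.6), access-start dates uniform over a 450-day enrolment span,
  lockdown days ~ Gamma(2, 25), downtime days uniform 0–14. A small
  missingness rate (0.02) is planted in survey-derived columns.
* **Latent propensity** — η_i = Σ β_k(x_ik − x̄_k) + ε_i, ε ~ N(0, 1), with
  default planted β: university +0.5, work hours −0.02/h, partner −0.4,
  siblings −0.4, regional −0.35, coping +0.4, all else 0. One η drives
  retention, session intensity and component diversity, so a planted effect
  shows up concordantly across all outcomes. η is computed from the
  *observed* cohort table (mean-imputing planted missing cells), so planted
  effects are mildly attenuated exactly the way a real analysis would be.
* **Uptake** — P(nonuser) = expit(c + −0.5·coping_c − 0.08·concern_c) with
  c solved so the cohort mean is 0.107; 8.2 % of nonusers are login-only.
* **Retention** — P(active in week w) = expit(θ₀ + θ₁(w−1) + η). θ₀ and θ₁
  are solved per cohort (bisection on the sample-mean equation over the
  realized η of users) so week-1 access averages 0.906 and week-25 access
  0.312. Solving on the realized sample rather than freezing numbers makes
  the calibration hold for any planted-effect configuration. A user whose 25
  Bernoulli draws all fail is forced active in week 1 (users have ≥1 event
  by definition); this affects ≪1 % of users.
* **Activity** — active weeks carry 1+Poisson(0.25·e^{0.3η}) sessions on
  random days; a session is a login followed by 1+Poisson(3.2·e^{0.25η})
  view/click events with exponential inter-event gaps (mean 25 s; see
  below), start hour uniform 06:00–22:00. Events are spread over
  module/toolkit/forum/faq with weights 0.70/0.19/0.06/0.05 restricted to
  each user's enabled components; ever-use flags are calibrated to
  0.829/0.55/0.291 the same way as uptake. Module events follow the
  sequential-unlock rule exactly (one open module; completable with
  probability 0.3 per active week once its minimum duration has elapsed), so
  generated logs pass the validator by construction.

The 25-second gap mean is a deliberate choice: at study-scale click volumes
a 2-minute gap convention would put mean total time in app several-fold
above the descriptive scale this generator targets (tens of minutes over 25
weeks). With the defaults, a default cohort averages ≈ 65 total minutes, 20
active days, ≈ 78/16/3 module/toolkit/forum clicks and 2.5 completed
modules — the right order of magnitude for this class of intervention.

What the generator does **not** emulate: page-level content semantics, SMS
prompts and their re-engagement effects, pandemic-wave geography,
within-user behavioural change beyond the monotone weekly trend, or
measurement of offline behaviour enactment. Passing tests therefore
demonstrate correctness of the pipeline's arithmetic and its statistical
operating characteristics under a plausible data-generating process — not
fidelity of any particular real cohort's raw distributions. In particular
the cohort-minmax EI mean of synthetic cohorts (≈ 52) is not comparable to
published EI means, which depend on unpublished raw distributions.

An optional confounding switch ties lockdown days to major-city residence
and feeds them into η, creating a planted indirect path that the sensitivity
adjustment should remove; it is off by default.

## Numerical and degenerate-input choices

* Cohort intercept calibration uses Brent bisection on
  mean(expit(c + offsets)) − target, tolerance 1e-10.
* Min–max with zero range → all users 50; theoretical-max with zero cohort
  maximum → 50 likewise.
* Sorting of events is stable everywhere; tied timestamps keep on-disk order.
* Zero-variance predictors and models with < 10 complete cases are flagged
  `estimable=False` with NaN estimates instead of being silently dropped.
* Chi-square tests use no continuity correction, so the statistic equals the
  textbook Σ(O−E)²/E; t tests are classic equal-variance two-sample t.
* All randomness flows from one integer seed through named substreams
  (cohort, events), so cohort and log are independently reproducible.

## Problem sizes used in validation

Calibration checks average 20 generated cohorts at the default n=682.
Parameter-recovery and null-error-rate checks run 200 replicates at n=600
(sign recovery ≥ 95 % for university/siblings/work-hours; pooled null
rejection rate within [0.02, 0.08], a ±3σ band around α=0.05 for ~600
pooled tests). Brute-force oracle equivalence uses ≤ 50-event fixtures at
1e-8 relative tolerance.

## Known limitations

* The EI's cohort-relative default normalization means EI values are not
  transportable across cohorts; use `theoretical-max` when comparability
  matters more than within-cohort discrimination.
* Complete-case screening makes per-model n vary and is biased when
  missingness is informative; no imputation is provided by design.
* The sequential-unlock validator assumes completion is observable as
  `complete_activity` events; logs from backends that record completion
  differently need mapping first.
* The generator's within-week timing model (uniform start hour, exponential
  gaps) is a convention; only sessionization-derived quantities are
  sensitive to it.
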