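"""Synthetic cohort and event-log generator with planted covariate effects.

The generator emulates the statistical structure of a parental mHealth
intervention cohort so that the whole analysis pipeline can be exercised and
validated offline:

* **Cohort marginals** follow the study population the defaults describe —
  mostly mothers in their mid-30s, ~72% university educated, ~72% in major
  cities, coping ~ N(3.2, 0.7) clipped to [1, 5], a 4-item movement-behavior
  concern score summing to ~7.3 (SD ~2.6), right-skewed information-seeking
  hours, staggered access-start dates, lockdown and app-downtime days.
* **A single latent engagement propensity** eta_i = sum_k beta_k x_ik + eps_i
  drives weekly app access, session intensity and component diversity, so a
  planted covariate effect manifests concordantly across all engagement
  outcomes. Default planted signs: university +, work hours -, cohabiting
  partner -, siblings -, regional residence -, coping +.
* **Uptake**: each enrollee is a nonuser with probability ~10.7% at baseline
  (never logs in, or logs in once and goes no further), decreasing in coping
  and concern.
* **Retention**: a user is active in week w with probability
  inverse-logit(theta0 + theta1 (w-1) + eta_i). The intercept and slope are
  calibrated against the realized eta sample so the cohort-level access
  fraction is ~90.6% in week 1 and ~31.2% in week 25.
* **Activity**: active weeks contain 1+Poisson sessions; each session is a
  login followed by 1+Poisson page views with exponential inter-event gaps,
  spread over pages and features of the components that user ever touches
  (module/toolkit/forum "ever" fractions calibrated to 82.9/55/29.1%).
  Module events follow the sequential-unlock rule: one open module at a
  time, completable only after its minimum duration has elapsed.

Intercept calibration solves, by bisection, the sample-mean equation
mean_i(inverse-logit(c + offset_i)) = target on the realized offsets, so the
targets hold in expectation for every generated cohort.
"""

from __future__ import annotations

import datetime as dt
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field
from scipy.optimize import brentq
from scipy.special import expit, ndtr

from .events import EVENT_COLUMNS, AppContent, default_content

_COHORT_STREAM = 1
_EVENT_STREAM = 2

#: Cohort columns that may carry planted nonzero effects on the latent
#: propensity (values are the covariates as the regression module codes them).
EFFECT_COVARIATES = [
    "parent_age", "australian_born", "university_degree", "work_hours",
    "partner_cohabiting", "siblings_in_family", "regional", "seifa_score",
    "coping", "concern_total", "info_seek_total",
]


class CovariateParams(BaseModel):
    """Marginal distributions of the baseline covariates."""

    university: float = Field(0.718, ge=0, le=1)
    mother: float = Field(0.982, ge=0, le=1)
    australian_born: float = Field(0.767, ge=0, le=1)
    working: float = Field(0.649, ge=0, le=1)
    partner: float = Field(0.924, ge=0, le=1)
    siblings: float = Field(0.588, ge=0, le=1)
    major_city: float = Field(0.718, ge=0, le=1)
    inner_regional: float = Field(0.192, ge=0, le=1)
    child_female: float = Field(0.494, ge=0, le=1)
    temperament_probs: tuple[float, float, float] = (0.324, 0.529, 0.147)
    age_mean: float = 34.9
    age_sd: float = 4.5
    coping_mean: float = 3.2
    coping_sd: float = 0.7
    #: 5-point concern item distribution; item correlation via a shared factor.
    concern_item_probs: tuple[float, ...] = (0.52, 0.26, 0.11, 0.07, 0.04)
    concern_item_corr: float = Field(0.3, ge=0, le=1)
    #: info seeking: point mass at zero plus a right-skewed gamma tail,
    #: targeting mean ~2.2 h/wk with SD ~4.6, clipped to [0, 40].
    info_seek_zero: float = Field(0.45, ge=0, le=1)
    info_seek_shape: float = 0.5
    info_seek_scale: float = 8.0
    work_hours_mean: float = 30.0
    work_hours_sd: float = 10.0
    seifa_mean: float = 1004.0
    seifa_sd: float = 65.0


class NonuserParams(BaseModel):
    """Uptake model: probability of never becoming a user."""

    baseline: float = Field(0.107, ge=0, le=1)
    coef_coping: float = -0.5
    coef_concern: float = -0.08
    #: among nonusers, share who log in once but never use a feature (6/73).
    login_only_share: float = Field(0.082, ge=0, le=1)


class RetentionParams(BaseModel):
    """Weekly access model; intercept/slope solved against these targets."""

    week1_target: float = Field(0.906, gt=0, lt=1)
    week25_target: float = Field(0.312, gt=0, lt=1)
    eta_loading: float = 1.0


class ActivityParams(BaseModel):
    """Within-week usage intensity and component mix."""

    sessions_rate: float = 0.25
    sessions_eta_loading: float = 0.3
    views_rate: float = 3.2
    views_eta_loading: float = 0.25
    module_ever: float = Field(0.829, ge=0, le=1)
    toolkit_ever: float = Field(0.55, ge=0, le=1)
    forum_ever: float = Field(0.291, ge=0, le=1)
    ever_eta_loading: float = 0.8
    #: relative weights of module/toolkit/forum/faq events for a user with
    #: all components enabled (renormalized over the enabled set; faq always on).
    component_weights: tuple[float, float, float, float] = (0.70, 0.19, 0.06, 0.05)
    complete_prob: float = Field(0.30, ge=0, le=1)
    feature_prob: float = Field(0.65, ge=0, le=1)
    click_share: float = Field(0.2, ge=0, le=1)
    forum_action_probs: tuple[float, float, float, float] = (0.60, 0.15, 0.13, 0.12)
    gap_mean_seconds: float = 25.0
    start_hour: tuple[float, float] = (6.0, 22.0)


class PlantedEffects(BaseModel):
    """Coefficients linking covariates to the latent propensity eta."""

    parent_age: float = 0.0
    australian_born: float = 0.0
    university_degree: float = 0.5
    work_hours: float = -0.02
    partner_cohabiting: float = -0.4
    siblings_in_family: float = -0.4
    regional: float = -0.35
    seifa_score: float = 0.0
    coping: float = 0.4
    concern_total: float = 0.0
    info_seek_total: float = 0.0
    eta_sd: float = Field(1.0, ge=0)

    def as_series(self) -> pd.Series:
        return pd.Series({k: getattr(self, k) for k in EFFECT_COVARIATES})

    @classmethod
    def null(cls) -> "PlantedEffects":
        return cls(**{k: 0.0 for k in EFFECT_COVARIATES})


class ConfoundingParams(BaseModel):
    """Optional confounding switch for sensitivity-analysis testing.

    When enabled, lockdown days depend on living in a major city (as they did
    during the pandemic) and directly depress the latent propensity, making
    ``regional`` a confounded predictor until lockdown is adjusted for.
    """

    enabled: bool = False
    lockdown_city_extra_days: float = 60.0
    lockdown_eta_per_day: float = -0.01


class GeneratorParams(BaseModel):
    """All knobs of the synthetic generator; defaults define the reference
    study conditions (682 enrollees, 25-week window)."""

    n_enrollees: int = Field(682, ge=1)
    window_days: int = 175
    covariates: CovariateParams = Field(default_factory=CovariateParams)
    nonuser: NonuserParams = Field(default_factory=NonuserParams)
    retention: RetentionParams = Field(default_factory=RetentionParams)
    activity: ActivityParams = Field(default_factory=ActivityParams)
    effects: PlantedEffects = Field(default_factory=PlantedEffects)
    confounding: ConfoundingParams = Field(default_factory=ConfoundingParams)
    missing_rate: float = Field(0.02, ge=0, le=1)
    enrol_start: dt.date = dt.date(2021, 3, 1)
    enrol_span_days: int = 450
    lockdown_shape: float = 2.0
    lockdown_scale: float = 25.0
    downtime_max_days: int = 15

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(yaml.safe_load(self.model_dump_json()), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorParams":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))


def planted_truth(params: GeneratorParams) -> pd.DataFrame:
    """Ground-truth effect table: the exact beta used by the generator, plus
    the direction each covariate is expected to show on every engagement
    outcome (all outcomes load positively on eta)."""
    beta = params.effects.as_series()
    return pd.DataFrame({
        "covariate": beta.index,
        "beta": beta.to_numpy(),
        "expected_direction": np.sign(beta.to_numpy()).astype(int),
    })


def solve_intercept(offsets: np.ndarray, target: float,
                    lo: float = -30.0, hi: float = 30.0) -> float:
    """Solve mean(expit(c + offsets)) == target for the intercept c."""
    if not 0.0 < target < 1.0:
        raise ValueError("target must be in (0, 1)")
    f = lambda c: float(np.mean(expit(c + offsets))) - target
    return float(brentq(f, lo, hi, xtol=1e-10))


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def generate_cohort(params: GeneratorParams, seed: int) -> pd.DataFrame:
    """Draw a cohort table with the configured covariate marginals.

    Reproducible given (params, seed); missing cells (rate ``missing_rate``)
    are planted in the survey-derived columns to exercise complete-case
    handling downstream.
    """
    cv = params.covariates
    if cv.major_city + cv.inner_regional > 1.0 + 1e-9:
        raise ValueError("remoteness probabilities exceed 1")
    rng = _rng(seed, _COHORT_STREAM)
    n = params.n_enrollees

    user_id = np.array([f"u{i:05d}" for i in range(1, n + 1)])
    parent_age = np.round(np.clip(rng.normal(cv.age_mean, cv.age_sd, n), 21, 48), 1)
    is_mother = (rng.random(n) < cv.mother).astype(float)
    australian_born = (rng.random(n) < cv.australian_born).astype(float)
    university = (rng.random(n) < cv.university).astype(float)
    working = rng.random(n) < cv.working
    work_hours = np.where(
        working, np.round(np.clip(rng.normal(cv.work_hours_mean, cv.work_hours_sd, n), 4, 50), 1),
        0.0)
    partner = (rng.random(n) < cv.partner).astype(float)
    siblings = (rng.random(n) < cv.siblings).astype(float)
    rem_probs = [cv.major_city, cv.inner_regional,
                 1.0 - cv.major_city - cv.inner_regional]
    remoteness = rng.choice(
        ["major_city", "inner_regional", "outer_regional_remote"], size=n, p=rem_probs)
    seifa = np.round(np.clip(rng.normal(cv.seifa_mean, cv.seifa_sd, n), 800, 1200), 0)
    coping = np.round(np.clip(rng.normal(cv.coping_mean, cv.coping_sd, n), 1, 5), 2)

    # 4 correlated ordinal concern items via a Gaussian copula with a shared factor.
    rho = cv.concern_item_corr
    factor = rng.normal(size=(n, 1))
    z = np.sqrt(rho) * factor + np.sqrt(1 - rho) * rng.normal(size=(n, 4))
    cuts = np.cumsum(cv.concern_item_probs)[:-1]
    concern_items = 1 + np.searchsorted(cuts, ndtr(z).ravel()).reshape(n, 4)

    zero_mask = rng.random(n) < cv.info_seek_zero
    info_total = np.where(
        zero_mask, 0.0,
        rng.gamma(cv.info_seek_shape, cv.info_seek_scale, n))
    info_total = np.clip(info_total, 0.0, 40.0)
    shares = rng.dirichlet(np.ones(3), size=n)
    info_items = np.round(info_total[:, None] * shares, 2)

    child_female = (rng.random(n) < cv.child_female).astype(float)
    temperament = rng.choice(list(("easier", "average", "more_difficult")),
                             size=n, p=np.asarray(cv.temperament_probs) /
                             np.sum(cv.temperament_probs))

    start_offsets = rng.integers(0, params.enrol_span_days, n)
    access_start = (pd.Timestamp(params.enrol_start, tz="UTC")
                    + pd.to_timedelta(start_offsets, unit="D"))

    lockdown = np.round(rng.gamma(params.lockdown_shape, params.lockdown_scale, n))
    if params.confounding.enabled:
        lockdown = lockdown + params.confounding.lockdown_city_extra_days * (
            remoteness == "major_city")
    lockdown = np.clip(lockdown, 0, 180)
    downtime = rng.integers(0, params.downtime_max_days, n).astype(float)

    cohort = pd.DataFrame({
        "user_id": user_id,
        "parent_age": parent_age,
        "is_mother": is_mother,
        "australian_born": australian_born,
        "university_degree": university,
        "work_hours": work_hours,
        "partner_cohabiting": partner,
        "siblings_in_family": siblings,
        "remoteness": remoteness,
        "seifa_score": seifa,
        "coping": coping,
        "concern_sitting": concern_items[:, 0].astype(float),
        "concern_activity": concern_items[:, 1].astype(float),
        "concern_screen": concern_items[:, 2].astype(float),
        "concern_sleep": concern_items[:, 3].astype(float),
        "info_seek_activity": info_items[:, 0],
        "info_seek_screen": info_items[:, 1],
        "info_seek_sleep": info_items[:, 2],
        "child_female": child_female,
        "child_temperament": temperament,
        "access_start": access_start,
        "lockdown_days": lockdown,
        "downtime_days": downtime,
    })

    if params.missing_rate > 0:
        missable = ["australian_born", "partner_cohabiting", "work_hours",
                    "seifa_score", "coping", *[
                        "concern_sitting", "concern_activity",
                        "concern_screen", "concern_sleep"],
                    "info_seek_activity", "info_seek_screen", "info_seek_sleep",
                    "child_temperament"]
        for col in missable:
            mask = rng.random(n) < params.missing_rate
            cohort.loc[mask, col] = np.nan
    return cohort


def _latent_propensity(cohort: pd.DataFrame, params: GeneratorParams,
                       rng: np.random.Generator) -> np.ndarray:
    """eta_i = sum_k beta_k (x_ik - mean) + eps_i, from the observed cohort.

    Missing covariate values contribute their cohort mean (zero after
    centering), so the planted effect is mildly attenuated by missingness —
    the same direction of attenuation a real analysis would face.
    """
    beta = params.effects.as_series()
    X = pd.DataFrame(index=cohort.index)
    X["parent_age"] = cohort["parent_age"]
    X["australian_born"] = cohort["australian_born"]
    X["university_degree"] = cohort["university_degree"]
    X["work_hours"] = cohort["work_hours"]
    X["partner_cohabiting"] = cohort["partner_cohabiting"]
    X["siblings_in_family"] = cohort["siblings_in_family"]
    X["regional"] = (cohort["remoteness"] != "major_city").astype(float).where(
        cohort["remoteness"].notna())
    X["seifa_score"] = cohort["seifa_score"]
    X["coping"] = cohort["coping"]
    X["concern_total"] = cohort[["concern_sitting", "concern_activity",
                                 "concern_screen", "concern_sleep"]].sum(axis=1, min_count=4)
    X["info_seek_total"] = cohort[["info_seek_activity", "info_seek_screen",
                                   "info_seek_sleep"]].sum(axis=1, min_count=3)
    Xc = (X - X.mean()).fillna(0.0)
    eta = Xc.to_numpy() @ beta.to_numpy()
    if params.confounding.enabled:
        ld = cohort["lockdown_days"].fillna(cohort["lockdown_days"].mean())
        eta = eta + params.confounding.lockdown_eta_per_day * (ld - ld.mean()).to_numpy()
    return eta + rng.normal(0.0, params.effects.eta_sd, len(cohort))


def generate_event_log(cohort: pd.DataFrame, content: AppContent,
                       params: GeneratorParams, seed: int) -> pd.DataFrame:
    """Simulate the event log for a cohort.

    Nonusers emit at most a single login; users emit weekly sessions under
    the calibrated retention model, and module events respect the sequential
    unlock rule and per-module minimum durations. All events fall inside each
    user's observation window.
    """
    if not content.modules:
        raise ValueError("content has no modules")
    rng = _rng(seed, _EVENT_STREAM)
    act = params.activity
    n = len(cohort)
    n_weeks = params.window_days // 7

    eta_all = _latent_propensity(cohort, params, rng)

    # --- uptake: nonuser draw, decreasing in coping and concern -------------
    coping_c = (cohort["coping"] - cohort["coping"].mean()).fillna(0.0).to_numpy()
    concern = cohort[["concern_sitting", "concern_activity",
                      "concern_screen", "concern_sleep"]].sum(axis=1, min_count=4)
    concern_c = (concern - concern.mean()).fillna(0.0).to_numpy()
    nu = params.nonuser
    offsets = nu.coef_coping * coping_c + nu.coef_concern * concern_c
    c0 = solve_intercept(offsets, nu.baseline)
    nonuser = rng.random(n) < expit(c0 + offsets)
    login_only = nonuser & (rng.random(n) < nu.login_only_share)

    users = np.flatnonzero(~nonuser)
    nu_users = len(users)
    eta = params.retention.eta_loading * eta_all[users]

    # --- retention: weekly access probabilities calibrated on eta -----------
    ret = params.retention
    c1 = solve_intercept(eta, ret.week1_target)
    c_last = solve_intercept(eta, ret.week25_target)
    slope = (c_last - c1) / max(n_weeks - 1, 1)
    weeks = np.arange(n_weeks)
    p_active = expit(c1 + slope * weeks[None, :] + eta[:, None])
    active = rng.random((nu_users, n_weeks)) < p_active
    never = ~active.any(axis=1)
    active[never, 0] = True  # a user, by definition, shows up at least once

    # --- per-user component mix --------------------------------------------
    ever_off = act.ever_eta_loading * eta
    enabled = np.ones((nu_users, 4), dtype=bool)  # module, toolkit, forum, faq
    for j, target in enumerate([act.module_ever, act.toolkit_ever, act.forum_ever]):
        cj = solve_intercept(ever_off, target)
        enabled[:, j] = rng.random(nu_users) < expit(cj + ever_off)
    weights = np.asarray(act.component_weights) * enabled
    weights = weights / weights.sum(axis=1, keepdims=True)
    cum_w = np.cumsum(weights, axis=1)

    # --- sessions -----------------------------------------------------------
    sess_lam = act.sessions_rate * np.exp(act.sessions_eta_loading * eta)
    n_sess_uw = np.where(active, 1 + rng.poisson(sess_lam[:, None], (nu_users, n_weeks)), 0)
    u_idx, w_idx = np.nonzero(n_sess_uw)
    sess_user = np.repeat(u_idx, n_sess_uw[u_idx, w_idx])
    sess_week = np.repeat(w_idx, n_sess_uw[u_idx, w_idx])
    S = len(sess_user)
    sess_day = sess_week * 7 + rng.integers(0, 7, S)
    h0, h1 = act.start_hour
    sess_start = sess_day * 86400.0 + rng.uniform(h0 * 3600.0, h1 * 3600.0, S)

    # --- module timeline (sequential unlock) --------------------------------
    durations = np.array([m.min_duration_weeks for m in content.modules])
    n_mod = len(durations)
    cur_mod = np.full((nu_users, n_weeks), -1, dtype=int)
    comp_draw = rng.random((nu_users, n_weeks))
    completions: list[tuple[int, int, int]] = []  # (user_pos, week, module_idx)
    module_on = enabled[:, 0]
    for u in range(nu_users):
        if not module_on[u]:
            continue
        cur, start_week = 0, None
        for w in np.flatnonzero(active[u]):
            if cur >= n_mod:
                cur_mod[u, w] = n_mod - 1  # revisiting completed content
                continue
            if start_week is None:
                start_week = w
            cur_mod[u, w] = cur
            if (w - start_week + 1) >= durations[cur] and comp_draw[u, w] < act.complete_prob:
                completions.append((u, w, cur))
                cur += 1
                start_week = w + 1

    # --- page-view events ---------------------------------------------------
    view_lam = act.views_rate * np.exp(act.views_eta_loading * eta)
    n_views = 1 + rng.poisson(view_lam[sess_user])
    V = int(n_views.sum())
    view_sess = np.repeat(np.arange(S), n_views)
    view_user = sess_user[view_sess]

    gaps = rng.exponential(act.gap_mean_seconds, V)
    cs = np.cumsum(gaps)
    first = np.cumsum(n_views) - n_views
    view_off = cs - np.repeat(cs[first] - gaps[first], n_views)
    view_time = sess_start[view_sess] + view_off

    u01 = rng.random(V)
    comp_idx = (u01[:, None] > cum_w[view_user][:, :3]).sum(axis=1)  # 0..3

    # id pools per component
    def _pool(ids: list[str]) -> tuple[np.ndarray, int]:
        arr = np.array(ids, dtype=object)
        return arr, len(arr)

    mod_pages = [np.array(m.pages if m.pages else [f"{m.module_id}_p"], dtype=object)
                 for m in content.modules]
    mod_acts = [np.array(m.activities, dtype=object) for m in content.modules]
    tk_pages, n_tkp = _pool([p for p, c in content.pages.items() if c == "toolkit"])
    tk_feats, n_tkf = _pool([f for f, c in content.features.items() if c == "toolkit"])
    fo_pages, n_fop = _pool([p for p, c in content.pages.items() if c == "forum"])
    fo_feats, n_fof = _pool([f for f, c in content.features.items() if c == "forum"])
    fq_pages, n_fqp = _pool([p for p, c in content.pages.items() if c == "faq"])
    fq_feats, n_fqf = _pool([f for f, c in content.features.items() if c == "faq"])

    page_id = np.full(V, np.nan, dtype=object)
    feature_id = np.full(V, np.nan, dtype=object)
    module_col = np.full(V, np.nan, dtype=object)
    action = np.full(V, "page_view", dtype=object)
    component = np.array(["module", "toolkit", "forum", "faq"], dtype=object)[comp_idx]

    pick = rng.random(V)
    feat_mask = rng.random(V) < act.feature_prob
    click_mask = rng.random(V) < act.click_share

    # users without the module component have zero module weight; route any
    # residual module draw (u01 == 0 exactly) to faq as a safety net
    m_lookup = cur_mod[view_user, sess_week[view_sess]]
    stray = (comp_idx == 0) & (m_lookup < 0)
    comp_idx[stray] = 3
    component[stray] = "faq"

    is_mod = comp_idx == 0
    if is_mod.any():
        m_of_view = m_lookup[is_mod]
        lens_p = np.array([len(p) for p in mod_pages])
        lens_a = np.array([len(a) for a in mod_acts])
        flat_p = np.concatenate(mod_pages)
        flat_a = np.concatenate(mod_acts)
        off_p = np.concatenate([[0], np.cumsum(lens_p)[:-1]])
        off_a = np.concatenate([[0], np.cumsum(lens_a)[:-1]])
        sel = pick[is_mod]
        page_id[is_mod] = flat_p[off_p[m_of_view] +
                                 (sel * lens_p[m_of_view]).astype(int)]
        feature_id[is_mod] = flat_a[off_a[m_of_view] +
                                    (sel * lens_a[m_of_view]).astype(int)]
        feature_id[is_mod & ~feat_mask] = np.nan
        module_col[is_mod] = np.array([m.module_id for m in content.modules],
                                      dtype=object)[m_of_view]

    for mask, pages_arr, np_, feats_arr, nf_ in [
        (comp_idx == 1, tk_pages, n_tkp, tk_feats, n_tkf),
        (comp_idx == 3, fq_pages, n_fqp, fq_feats, n_fqf),
    ]:
        if mask.any():
            if np_:
                page_id[mask] = pages_arr[(pick[mask] * np_).astype(int)]
            if nf_:
                fm = mask & feat_mask
                feature_id[fm] = feats_arr[(pick[fm] * nf_).astype(int)]

    is_forum = comp_idx == 2
    if is_forum.any() and n_fop and n_fof:
        page_id[is_forum] = fo_pages[(pick[is_forum] * n_fop).astype(int)]
        fa = np.cumsum(act.forum_action_probs)[:3]
        a_idx = (rng.random(int(is_forum.sum()))[:, None] > fa[None, :]).sum(axis=1)
        action[is_forum] = np.array(["page_view", "post", "like", "comment"],
                                    dtype=object)[a_idx]
        fm = is_forum & feat_mask
        feature_id[fm] = fo_feats[(pick[fm] * n_fof).astype(int)]
        # posts/likes/comments always reference the forum feature they act on
        act_mask = is_forum & (action != "page_view")
        feature_id[act_mask] = fo_feats[(pick[act_mask] * n_fof).astype(int)]

    nonforum_click = click_mask & ~is_forum & feat_mask
    action[nonforum_click] = "click"

    # --- completion events --------------------------------------------------
    sess_end = sess_start.copy()
    if V:
        np.maximum.at(sess_end, view_sess, view_time)
    last_sess: dict[tuple[int, int], float] = {}
    for s in range(S):
        key = (int(sess_user[s]), int(sess_week[s]))
        t = sess_end[s]
        if key not in last_sess or t > last_sess[key]:
            last_sess[key] = t
    comp_user, comp_time, comp_feat, comp_mod = [], [], [], []
    for (u, w, m) in completions:
        base = last_sess[(u, w)]
        for k, a in enumerate(content.modules[m].activities):
            comp_user.append(u)
            comp_time.append(base + 20.0 * (k + 1))
            comp_feat.append(a)
            comp_mod.append(content.modules[m].module_id)

    # --- assemble -----------------------------------------------------------
    uid_arr = cohort["user_id"].to_numpy()
    user_ids_users = uid_arr[users]
    max_sec = params.window_days * 86400.0 - 1.0

    lo_idx = np.flatnonzero(login_only)
    lo_time = (rng.integers(0, 14, len(lo_idx)) * 86400.0
               + rng.uniform(h0 * 3600.0, h1 * 3600.0, len(lo_idx)))

    seg_user = np.concatenate([
        user_ids_users[sess_user], user_ids_users[view_user],
        user_ids_users[np.array(comp_user, dtype=int)] if comp_user else np.array([], dtype=object),
        uid_arr[lo_idx],
    ])
    seg_sec = np.concatenate([
        sess_start, view_time,
        np.array(comp_time, dtype=float), lo_time,
    ])
    seg_sec = np.minimum(seg_sec, max_sec)
    n_login, n_comp = S, len(comp_user)
    seg_page = np.concatenate([
        np.full(n_login, np.nan, dtype=object), page_id,
        np.full(n_comp, np.nan, dtype=object),
        np.full(len(lo_idx), np.nan, dtype=object),
    ])
    seg_feat = np.concatenate([
        np.full(n_login, np.nan, dtype=object), feature_id,
        np.array(comp_feat, dtype=object),
        np.full(len(lo_idx), np.nan, dtype=object),
    ])
    seg_comp = np.concatenate([
        np.full(n_login, "login", dtype=object), component,
        np.full(n_comp, "module", dtype=object),
        np.full(len(lo_idx), "login", dtype=object),
    ])
    seg_action = np.concatenate([
        np.full(n_login, "login", dtype=object), action,
        np.full(n_comp, "complete_activity", dtype=object),
        np.full(len(lo_idx), "login", dtype=object),
    ])
    seg_mod = np.concatenate([
        np.full(n_login, np.nan, dtype=object), module_col,
        np.array(comp_mod, dtype=object),
        np.full(len(lo_idx), np.nan, dtype=object),
    ])

    start_map = cohort.set_index("user_id")["access_start"]
    start_naive = (pd.DatetimeIndex(start_map.reindex(seg_user))
                   .tz_convert("UTC").tz_localize(None).to_numpy())
    timestamps = start_naive + np.floor(seg_sec).astype(np.int64).astype("timedelta64[s]")

    events = pd.DataFrame({
        "user_id": seg_user,
        "timestamp": pd.DatetimeIndex(timestamps).tz_localize("UTC"),
        "page_id": seg_page,
        "feature_id": seg_feat,
        "component": seg_comp,
        "action": seg_action,
        "module_id": seg_mod,
    })
    events = events.sort_values(["user_id", "timestamp"], kind="stable").reset_index(drop=True)
    return events[EVENT_COLUMNS]


def simulate_dataset(params: Optional[GeneratorParams] = None, seed: int = 0,
                     content: Optional[AppContent] = None,
                     ) -> tuple[pd.DataFrame, pd.DataFrame, AppContent, pd.DataFrame]:
    """Convenience wrapper: (cohort, events, content, effect table)."""
    params = params or GeneratorParams()
    content = content or default_content()
    cohort = generate_cohort(params, seed)
    events = generate_event_log(cohort, content, params, seed)
    return cohort, events, content, planted_truth(params)
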