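"""Predictor derivation and univariable regression screening.

Baseline survey covariates are turned into a predictor table (binary
predictors coded 0/1 with the less-engaged-looking category as reference:
no university degree, not Australian-born, major city, parents not
cohabiting, no siblings), a 4-item movement-behavior concern sum (range
4-20) and a total information-seeking time (clamped to 0-40 h/wk).

Each predictor x engagement-outcome pair is then fitted with its own simple
linear regression (one predictor per model, never a joint multivariable
fit), complete-case per model, with residual-t 95% confidence intervals and
two-sided p-values. Sensitivity variants re-fit each model with days in
lockdown or days of app downtime added as a covariate. No multiple-testing
adjustment is applied by default; Benjamini-Hochberg can be requested as a
post hoc column.

Users and nonusers are compared at baseline with chi-square tests
(categorical, no continuity correction) and t tests (numerical).
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .events import CONCERN_ITEMS, INFO_SEEK_ITEMS
from .metrics import STATUS_USER

#: Predictor columns, in the order the screening tables report them.
PREDICTORS = [
    "parent_age", "australian_born", "university_degree", "work_hours",
    "partner_cohabiting", "siblings_in_family", "regional", "seifa_score",
    "coping", "concern_total", "info_seek_total",
]

ASSOCIATION_COLUMNS = ["outcome", "predictor", "beta", "ci_low", "ci_high",
                       "p_value", "n_used", "model", "estimable", "p_adjusted"]


def derive_covariates(cohort: pd.DataFrame) -> pd.DataFrame:
    """Build the predictor table from the cohort, indexed by user_id.

    ``concern_total`` is the sum of the 4 concern items (missing if any item
    is missing); ``info_seek_total`` sums the per-topic hours and is clamped
    to [0, 40]; ``regional`` collapses inner and outer regional/remote
    against major cities. A concern item outside [1, 5] is a validation
    error.
    """
    for item in CONCERN_ITEMS:
        vals = pd.to_numeric(cohort[item], errors="coerce").dropna()
        if ((vals < 1) | (vals > 5)).any():
            raise ValueError(f"concern item {item!r} outside [1, 5]")
    out = pd.DataFrame(index=pd.Index(cohort["user_id"], name="user_id"))
    for col in ["parent_age", "australian_born", "university_degree", "work_hours",
                "partner_cohabiting", "siblings_in_family", "seifa_score", "coping"]:
        out[col] = pd.to_numeric(cohort[col], errors="coerce").to_numpy()
    rem = cohort["remoteness"]
    out["regional"] = (rem != "major_city").astype(float).where(rem.notna()).to_numpy()
    out["concern_total"] = cohort[CONCERN_ITEMS].sum(axis=1, min_count=len(CONCERN_ITEMS)).to_numpy()
    out["info_seek_total"] = (
        cohort[INFO_SEEK_ITEMS].sum(axis=1, min_count=len(INFO_SEEK_ITEMS))
        .clip(lower=0, upper=40).to_numpy())
    return out[PREDICTORS]


def _fit_one(y: np.ndarray, x: np.ndarray, extra: Optional[np.ndarray]) -> dict:
    X = x[:, None] if extra is None else np.column_stack([x, extra])
    X = sm.add_constant(X, has_constant="add")
    res = sm.OLS(y, X).fit()
    ci = res.conf_int(alpha=0.05)
    return {"beta": float(res.params[1]), "ci_low": float(ci[1][0]),
            "ci_high": float(ci[1][1]), "p_value": float(res.pvalues[1])}


def univariable_regressions(predictors: pd.DataFrame, outcomes: pd.DataFrame,
                            model_label: str = "unadjusted",
                            extra: Optional[pd.DataFrame] = None,
                            min_n: int = 10) -> pd.DataFrame:
    """One linear model per predictor x outcome, complete-case per model.

    ``extra`` holds optional adjuster column(s) (same index) added to every
    model. Models with fewer than ``min_n`` complete cases or a
    zero-variance predictor are flagged ``estimable=False`` with NaN
    estimates rather than dropped.
    """
    df = predictors.join(outcomes, how="inner")
    if extra is not None:
        df = df.join(extra, how="inner")
    extra_cols = list(extra.columns) if extra is not None else []
    records = []
    for out_col in outcomes.columns:
        for pred in predictors.columns:
            sub = df[[out_col, pred, *extra_cols]].dropna()
            rec = {"outcome": out_col, "predictor": pred, "beta": np.nan,
                   "ci_low": np.nan, "ci_high": np.nan, "p_value": np.nan,
                   "n_used": len(sub), "model": model_label, "estimable": False,
                   "p_adjusted": np.nan}
            x = sub[pred].to_numpy(float)
            if len(sub) >= min_n and np.ptp(x) > 0:
                ex = sub[extra_cols].to_numpy(float) if extra_cols else None
                rec.update(_fit_one(sub[out_col].to_numpy(float), x, ex))
                rec["estimable"] = True
            records.append(rec)
    return pd.DataFrame.from_records(records, columns=ASSOCIATION_COLUMNS)


def sensitivity_regressions(predictors: pd.DataFrame, outcomes: pd.DataFrame,
                            cohort: pd.DataFrame,
                            adjusters: Sequence[str] = ("lockdown_days", "downtime_days"),
                            joint: bool = False, min_n: int = 10) -> pd.DataFrame:
    """Re-fit every model with lockdown / downtime adjustment.

    By default each adjuster enters a separate model variant
    (``adj_lockdown``, ``adj_downtime``); ``joint=True`` instead fits one
    variant with all adjusters together.
    """
    adj_tab = cohort.set_index("user_id")[list(adjusters)].apply(
        pd.to_numeric, errors="coerce")
    if joint:
        label = "adj_" + "_".join(a.removesuffix("_days") for a in adjusters)
        return univariable_regressions(predictors, outcomes, model_label=label,
                                       extra=adj_tab, min_n=min_n)
    frames = []
    for a in adjusters:
        label = "adj_" + a.removesuffix("_days")
        frames.append(univariable_regressions(
            predictors, outcomes, model_label=label, extra=adj_tab[[a]], min_n=min_n))
    return pd.concat(frames, ignore_index=True)


def benjamini_hochberg(records: pd.DataFrame) -> pd.DataFrame:
    """Optional extension: fill ``p_adjusted`` with BH-FDR values, adjusted
    within each (model, outcome) family. Raw p-values are left untouched."""
    from statsmodels.stats.multitest import multipletests

    out = records.copy()
    for _, idx in out.groupby(["model", "outcome"]).groups.items():
        p = out.loc[idx, "p_value"]
        ok = p.notna().to_numpy()
        if ok.any():
            out.loc[np.asarray(idx)[ok], "p_adjusted"] = multipletests(
                p.to_numpy()[ok], method="fdr_bh")[1]
    return out


def compare_users_nonusers(predictors: pd.DataFrame, status: pd.DataFrame) -> pd.DataFrame:
    """Baseline comparison of users vs nonusers, one row per predictor.

    Binary predictors get a chi-square test on the 2x2 table (no continuity
    correction); numerical predictors get a two-sample t test. Groups too
    small to test are flagged ``estimable=False``.
    """
    st = status.set_index("user_id")["status"].reindex(predictors.index)
    is_user = (st == STATUS_USER).to_numpy()
    if is_user.all() or (~is_user).all():
        raise ValueError("both user and nonuser groups must be non-empty")
    records = []
    for col in predictors.columns:
        x = predictors[col]
        ok = x.notna().to_numpy()
        xu, xn = x[ok & is_user], x[ok & ~is_user]
        vals = x[ok].unique()
        binary = len(vals) <= 2 and set(np.unique(vals)).issubset({0.0, 1.0})
        rec = {"variable": col,
               "test": "chi_square" if binary else "t_test",
               "user_value": float(xu.mean()) if len(xu) else np.nan,
               "nonuser_value": float(xn.mean()) if len(xn) else np.nan,
               "statistic": np.nan, "p_value": np.nan, "estimable": False}
        if binary:
            table = np.array([[(xu == 1).sum(), (xu == 0).sum()],
                              [(xn == 1).sum(), (xn == 0).sum()]], dtype=float)
            if (table.sum(axis=1) > 0).all() and (table.sum(axis=0) > 0).all():
                chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
                rec.update(statistic=float(chi2), p_value=float(p), estimable=True)
        else:
            if len(xu) >= 2 and len(xn) >= 2:
                t, p = stats.ttest_ind(xu, xn, equal_var=True)
                rec.update(statistic=float(t), p_value=float(p), estimable=True)
        records.append(rec)
    return pd.DataFrame.from_records(records)
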