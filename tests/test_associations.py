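"""Covariate derivation, univariable screening, sensitivity models, comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from engagelog import (GeneratorParams, benjamini_hochberg,
                       compare_users_nonusers, derive_covariates,
                       sensitivity_regressions, univariable_regressions)
from engagelog.associations import PREDICTORS

from conftest import make_cohort
from oracles import chi_square_by_hand, ols_normal_equations


class TestDeriveCovariates:
    @pytest.mark.parametrize("items, total", [((1, 1, 1, 1), 4.0), ((5, 5, 5, 5), 20.0),
                                              ((2, 3, 1, 4), 10.0)])
    def test_concern_total_is_item_sum(self, items, total):
        cohort = make_cohort(["u1"], concern_sitting=float(items[0]),
                             concern_activity=float(items[1]),
                             concern_screen=float(items[2]),
                             concern_sleep=float(items[3]))
        assert derive_covariates(cohort).loc["u1", "concern_total"] == total

    def test_concern_item_out_of_range_rejected(self):
        cohort = make_cohort(["u1"], concern_sitting=6.0)
        with pytest.raises(ValueError, match="concern"):
            derive_covariates(cohort)

    @pytest.mark.parametrize("level, expected", [
        ("major_city", 0.0), ("inner_regional", 1.0), ("outer_regional_remote", 1.0)])
    def test_regional_collapses_non_metro(self, level, expected):
        cohort = make_cohort(["u1"], remoteness=level)
        assert derive_covariates(cohort).loc["u1", "regional"] == expected

    def test_missing_component_propagates(self):
        cohort = make_cohort(["u1"], concern_screen=np.nan, remoteness=np.nan)
        pred = derive_covariates(cohort)
        assert np.isnan(pred.loc["u1", "concern_total"])
        assert np.isnan(pred.loc["u1", "regional"])

    def test_info_seek_clamped_to_40(self):
        cohort = make_cohort(["u1"], info_seek_activity=30.0,
                             info_seek_screen=20.0, info_seek_sleep=5.0)
        assert derive_covariates(cohort).loc["u1", "info_seek_total"] == 40.0


class TestUnivariableRegressions:
    def test_noiseless_line_recovered_exactly(self):
        x = np.arange(20, dtype=float)
        pred = pd.DataFrame({"x": x}, index=[f"u{i}" for i in range(20)])
        outc = pd.DataFrame({"y": 2 * x + 1}, index=pred.index)
        rec = univariable_regressions(pred, outc).iloc[0]
        assert rec["beta"] == pytest.approx(2.0, abs=1e-10)
        assert rec["ci_high"] - rec["ci_low"] == pytest.approx(0.0, abs=1e-8)

    def test_cardinality_one_record_per_pair(self):
        rng = np.random.default_rng(0)
        idx = [f"u{i}" for i in range(30)]
        pred = pd.DataFrame(rng.normal(size=(30, 11)), index=idx, columns=PREDICTORS)
        outc = pd.DataFrame(rng.normal(size=(30, 12)), index=idx,
                            columns=[f"o{i}" for i in range(12)])
        rec = univariable_regressions(pred, outc)
        assert len(rec) == 132
        assert rec["estimable"].all()

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        n = 40
        idx = [f"u{i}" for i in range(n)]
        x = rng.normal(size=n)
        y = 1.5 * x + rng.normal(size=n)
        pred = pd.DataFrame({"x": x}, index=idx)
        outc = pd.DataFrame({"y": y}, index=idx)
        rec = univariable_regressions(pred, outc).iloc[0]
        exp = ols_normal_equations(x, y)
        for key in ("beta", "ci_low", "ci_high", "p_value"):
            assert rec[key] == pytest.approx(exp[key], rel=1e-8), key

    def test_complete_case_per_model(self):
        idx = [f"u{i}" for i in range(20)]
        pred = pd.DataFrame({"x1": np.arange(20.0), "x2": np.arange(20.0)}, index=idx)
        pred.loc["u3", "x2"] = np.nan
        outc = pd.DataFrame({"y": np.arange(20.0) + 1}, index=idx)
        rec = univariable_regressions(pred, outc).set_index("predictor")
        assert rec.loc["x1", "n_used"] == 20
        assert rec.loc["x2", "n_used"] == 19

    def test_zero_variance_predictor_flagged(self):
        idx = [f"u{i}" for i in range(15)]
        pred = pd.DataFrame({"x": 1.0}, index=idx)
        outc = pd.DataFrame({"y": np.arange(15.0)}, index=idx)
        rec = univariable_regressions(pred, outc).iloc[0]
        assert not rec["estimable"] and np.isnan(rec["beta"])

    def test_null_coverage_about_95pct(self):
        """With no true effect, the 95% CI covers zero ~95% of the time."""
        rng = np.random.default_rng(123)
        n, reps = 600, 200
        covered = 0
        idx = [f"u{i}" for i in range(n)]
        for _ in range(reps):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            rec = univariable_regressions(
                pd.DataFrame({"x": x}, index=idx),
                pd.DataFrame({"y": y}, index=idx)).iloc[0]
            covered += rec["ci_low"] <= 0 <= rec["ci_high"]
        assert 0.91 <= covered / reps <= 0.99

    def test_bh_adjustment_is_optional_column(self):
        rng = np.random.default_rng(1)
        idx = [f"u{i}" for i in range(25)]
        pred = pd.DataFrame(rng.normal(size=(25, 3)), index=idx, columns=list("abc"))
        outc = pd.DataFrame({"y": rng.normal(size=25)}, index=idx)
        rec = univariable_regressions(pred, outc)
        assert rec["p_adjusted"].isna().all()
        adj = benjamini_hochberg(rec)
        assert adj["p_adjusted"].notna().all()
        assert (adj["p_adjusted"] + 1e-12 >= adj["p_value"]).all()


class TestSensitivityRegressions:
    def _tables(self, rng, n=200, confound=False):
        idx = [f"u{i}" for i in range(n)]
        x = rng.normal(size=n)
        adjuster = rng.normal(size=n)
        if confound:
            adjuster = adjuster + 1.5 * x
            y = 1.0 * x + 2.0 * adjuster + rng.normal(size=n)
        else:
            y = 1.0 * x + rng.normal(size=n)
        pred = pd.DataFrame({"x": x}, index=idx)
        outc = pd.DataFrame({"y": y}, index=idx)
        cohort = make_cohort(idx, lockdown_days=adjuster, downtime_days=0.0)
        return pred, outc, cohort

    def test_independent_adjuster_leaves_beta(self):
        rng = np.random.default_rng(2)
        pred, outc, cohort = self._tables(rng)
        un = univariable_regressions(pred, outc).iloc[0]["beta"]
        adj = sensitivity_regressions(pred, outc, cohort,
                                      adjusters=["lockdown_days"]).iloc[0]
        assert adj["model"] == "adj_lockdown"
        assert adj["beta"] == pytest.approx(un, abs=0.15)

    def test_adjustment_removes_planted_confounding(self):
        rng = np.random.default_rng(3)
        pred, outc, cohort = self._tables(rng, confound=True)
        un = univariable_regressions(pred, outc).iloc[0]["beta"]
        adj = sensitivity_regressions(pred, outc, cohort,
                                      adjusters=["lockdown_days"]).iloc[0]["beta"]
        # direct effect is 1.0; unadjusted absorbs the indirect path (~+3)
        assert un > 2.5
        assert adj == pytest.approx(1.0, abs=0.25)

    def test_generator_confounding_switch(self):
        """With the simulator's confounding switch on, adjusting for lockdown
        moves the regional estimate toward its planted direct effect."""
        from engagelog import (ObservationWindow, classify_user_status,
                               compute_individual_metrics, default_content,
                               generate_cohort, generate_event_log)
        from engagelog.metrics import users_of

        params = GeneratorParams(
            n_enrollees=800, missing_rate=0.0,
            confounding={"enabled": True, "lockdown_city_extra_days": 80,
                         "lockdown_eta_per_day": -0.02})
        content = default_content()
        diffs = []
        for seed in (0, 1, 2):
            cohort = generate_cohort(params, seed)
            events = generate_event_log(cohort, content, params, seed)
            users = users_of(classify_user_status(events, cohort))
            window = ObservationWindow.from_cohort(cohort)
            m = compute_individual_metrics(
                events[events["user_id"].isin(set(users))], content, window, users=users)
            pred = derive_covariates(cohort).loc[users, ["regional"]]
            outc = m[["active_days"]]
            un = univariable_regressions(pred, outc).iloc[0]["beta"]
            adj = sensitivity_regressions(pred, outc, cohort,
                                          adjusters=["lockdown_days"]).iloc[0]["beta"]
            diffs.append(adj - un)
        # city dwellers get extra lockdown which suppresses engagement, so the
        # unadjusted regional coefficient is biased upward; adjustment lowers it
        assert np.mean(diffs) < 0

    def test_adjusted_n_never_exceeds_unadjusted(self):
        rng = np.random.default_rng(4)
        pred, outc, cohort = self._tables(rng, n=50)
        cohort.loc[3, "lockdown_days"] = np.nan
        un = univariable_regressions(pred, outc).iloc[0]["n_used"]
        adj = sensitivity_regressions(pred, outc, cohort,
                                      adjusters=["lockdown_days"]).iloc[0]["n_used"]
        assert adj <= un

    def test_joint_variant_label(self):
        rng = np.random.default_rng(6)
        pred, outc, cohort = self._tables(rng, n=60)
        rec = sensitivity_regressions(pred, outc, cohort, joint=True)
        assert set(rec["model"]) == {"adj_lockdown_downtime"}


class TestCompareUsersNonusers:
    def _status(self, idx, n_users):
        return pd.DataFrame({
            "user_id": idx,
            "status": ["user"] * n_users + ["nonuser_no_login"] * (len(idx) - n_users)})

    def test_identical_groups_not_significant(self):
        idx = [f"u{i}" for i in range(40)]
        vals = np.tile([1.0, 2.0, 3.0, 4.0], 10)
        pred = pd.DataFrame({"coping": vals}, index=idx)
        rec = compare_users_nonusers(pred, self._status(idx, 20)).iloc[0]
        assert rec["test"] == "t_test"
        assert abs(rec["statistic"]) < 1e-9
        assert rec["p_value"] == pytest.approx(1.0)

    def test_chi_square_matches_textbook_formula(self):
        # users: 20 with / 10 without; nonusers: 10 with / 20 without
        idx = [f"u{i}" for i in range(60)]
        x = np.r_[np.ones(20), np.zeros(10), np.ones(10), np.zeros(20)]
        pred = pd.DataFrame({"university_degree": x}, index=idx)
        rec = compare_users_nonusers(pred, self._status(idx, 30)).iloc[0]
        expected = chi_square_by_hand(np.array([[20, 10], [10, 20]]))
        assert rec["test"] == "chi_square"
        assert rec["statistic"] == pytest.approx(expected, rel=1e-12)
        chi2_ref, p_ref, _, _ = stats.chi2_contingency(
            np.array([[20, 10], [10, 20]]), correction=False)
        assert rec["p_value"] == pytest.approx(p_ref, rel=1e-12)

    def test_small_shift_detected_with_power(self):
        """A 0.2 SD coping shift at n=600/group is detected most of the time."""
        rng = np.random.default_rng(9)
        idx = [f"u{i}" for i in range(1200)]
        status = self._status(idx, 600)
        hits = 0
        reps = 60
        for _ in range(reps):
            x = np.r_[rng.normal(0.2, 1.0, 600), rng.normal(0.0, 1.0, 600)]
            pred = pd.DataFrame({"coping_like": x}, index=idx)
            rec = compare_users_nonusers(pred, status).iloc[0]
            hits += rec["p_value"] < 0.05
        assert hits / reps > 0.8  # theoretical power ~0.93

    def test_tiny_group_flagged(self):
        idx = [f"u{i}" for i in range(5)]
        pred = pd.DataFrame({"age": [30.0, 31, 32, 33, 34]}, index=idx)
        rec = compare_users_nonusers(pred, self._status(idx, 4)).iloc[0]
        assert not rec["estimable"]

    def test_requires_both_groups(self):
        idx = [f"u{i}" for i in range(4)]
        pred = pd.DataFrame({"age": [30.0, 31, 32, 33]}, index=idx)
        with pytest.raises(ValueError):
            compare_users_nonusers(pred, self._status(idx, 4))
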