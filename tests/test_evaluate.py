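import numpy as np
import pandas as pd
import pytest

from fiberscore import (
    CohortSimParams,
    build_nomogram,
    concordance_index,
    cox_regression,
    roc_at_horizon,
    score_to_dfs_curve,
    simulate_cohort,
    stratify_and_km,
    subgroup_report,
    time_dependent_auc,
)
from fiberscore.evaluate import EvaluationError
from fiberscore.scoring import efron_partial_loglik


def _ph_cohort(n=1000, beta=1.0, seed=0, censoring=0.3):
    return simulate_cohort(CohortSimParams(
        n_patients=n, beta={"x": beta}, censoring_target=censoring,
        admin_horizon_months=240.0, include_clinical=False, include_tacs=False,
        seed=seed))


class TestHorizonRoc:
    def test_perfect_score_auc_one(self):
        table = _ph_cohort(n=500, censoring=None, seed=1)
        t, e = table.outcomes()
        r = roc_at_horizon(-t, t, e, horizon=60, bootstrap_reps=0)
        assert r.auc == 1.0

    def test_negated_score_complements_auc(self):
        table = _ph_cohort(n=500, seed=2)
        t, e = table.outcomes()
        s = table.df["x"].to_numpy()
        a = roc_at_horizon(s, t, e, horizon=60, bootstrap_reps=0).auc
        b = roc_at_horizon(-s, t, e, horizon=60, bootstrap_reps=0).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_bootstrap_ci_brackets_point(self):
        table = _ph_cohort(n=300, seed=3)
        t, e = table.outcomes()
        r = roc_at_horizon(table.df["x"].to_numpy(), t, e, horizon=60,
                           bootstrap_reps=100, seed=0)
        assert r.ci_lower <= r.auc <= r.ci_upper

    def test_ci_width_shrinks_with_n(self):
        widths = {}
        for n in (200, 2000):
            table = _ph_cohort(n=n, seed=4)
            t, e = table.outcomes()
            r = roc_at_horizon(table.df["x"].to_numpy(), t, e, horizon=60,
                               bootstrap_reps=150, seed=0)
            widths[n] = r.ci_upper - r.ci_lower
        assert widths[2000] < widths[200]

    def test_no_cases_error(self):
        t = np.full(30, 100.0)
        e = np.zeros(30, int)
        with pytest.raises(EvaluationError):
            roc_at_horizon(np.arange(30.0), t, e, horizon=60, bootstrap_reps=0)

    def test_youden_cutoff_separates_groups(self):
        table = _ph_cohort(n=800, beta=2.0, seed=5)
        t, e = table.outcomes()
        r = roc_at_horizon(table.df["x"].to_numpy(), t, e, horizon=60,
                           bootstrap_reps=0)
        assert 0.0 <= r.sensitivity <= 1.0 and 0.0 <= r.specificity <= 1.0
        assert r.sensitivity + r.specificity > 1.0


class TestStratifyKm:
    def test_hand_worked_fixture(self, km_hand_fixture):
        fx = km_hand_fixture
        r = stratify_and_km(fx["group_high"], 0.5, fx["time"], fx["event"])
        assert r.logrank_chi2 == pytest.approx(fx["expected_chi2"], rel=1e-9)
        np.testing.assert_allclose(r.km_low["survival"], fx["expected_km_low"], rtol=1e-12)
        np.testing.assert_allclose(r.km_high["survival"], fx["expected_km_high"], rtol=1e-12)

    def test_no_events_signalled(self):
        t = np.linspace(1, 10, 8)
        e = np.zeros(8, int)
        with pytest.raises(EvaluationError, match="log-rank"):
            stratify_and_km(np.arange(8.0), 4.0, t, e)

    def test_exponential_hr_recovery(self):
        rng = np.random.default_rng(6)
        n = 1000
        grp = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1.0, n) / np.where(grp == 1, 3.0, 1.0)
        r = stratify_and_km(grp, 0.5, t, np.ones(n, int))
        assert r.hazard_ratio == pytest.approx(3.0, abs=0.4)

    def test_degenerate_cutoff_rejected(self):
        t = np.linspace(1, 10, 8)
        with pytest.raises(EvaluationError):
            stratify_and_km(np.ones(8), 0.0, t, np.ones(8, int))


class TestCoxRegression:
    def test_null_simulation_hr_near_one(self):
        table = _ph_cohort(n=1000, beta=0.0, seed=7)
        df = table.df
        res = cox_regression(df, ("x",))
        assert res[0].hr == pytest.approx(1.0, abs=0.15)
        assert res[0].ci_lower <= res[0].hr <= res[0].ci_upper

    def test_brute_force_grid_oracle_n6(self):
        t = np.array([1.0, 2, 3, 4, 5, 6])
        e = np.array([1, 1, 0, 1, 0, 1])
        x = np.array([0.5, -1.0, 2.0, 0.0, 1.5, -0.5])
        grid = np.arange(-3.0, 3.0 + 1e-9, 1e-3)
        lls = [efron_partial_loglik(b * x, t, e) for b in grid]
        beta_grid = grid[int(np.argmax(lls))]
        df = pd.DataFrame({"x": x, "dfs_months": t, "event": e})
        res = cox_regression(df, ("x",))
        assert abs(np.log(res[0].hr) - beta_grid) <= 1e-3 + 1e-6

    def test_duplicated_covariate_collinearity(self):
        table = _ph_cohort(n=200, seed=8)
        df = table.df.copy()
        df["x2"] = df["x"]
        with pytest.raises(EvaluationError, match="collinear"):
            cox_regression(df, ("x", "x2"), mode="multivariate")

    def test_multivariate_adjustment_recorded(self):
        table = simulate_cohort(CohortSimParams(
            n_patients=500, beta={"a": 1.0, "b": 0.0}, features=("a", "b"),
            censoring_target=0.3, admin_horizon_months=240.0,
            include_clinical=False, include_tacs=False, seed=9))
        res = cox_regression(table.df, ("a", "b"), mode="multivariate")
        assert res[0].adjusted_for == ("b",)
        assert res[0].p_value < 0.001 and res[1].p_value > 0.001


class TestTimeDependentAuc:
    def test_constant_auc_iauc_identity(self):
        table = _ph_cohort(n=500, censoring=None, seed=10)
        t, e = table.outcomes()
        grid = np.linspace(10, 100, 8)
        aucs, iauc = time_dependent_auc(-t, t, e, grid)
        np.testing.assert_allclose(aucs, 1.0)
        assert iauc == pytest.approx(1.0)

    def test_anticoncordant_complement(self):
        table = _ph_cohort(n=800, seed=11)
        t, e = table.outcomes()
        s = table.df["x"].to_numpy()
        grid = np.linspace(12, 90, 8)
        _, i1 = time_dependent_auc(s, t, e, grid)
        _, i2 = time_dependent_auc(-s, t, e, grid)
        assert i1 + i2 == pytest.approx(1.0, abs=1e-9)

    def test_matches_independent_estimator(self):
        # dual-implementation cross-check against scikit-survival's IPCW
        # cumulative/dynamic estimator on the same grid
        from sksurv.metrics import cumulative_dynamic_auc
        from sksurv.util import Surv

        table = _ph_cohort(n=2000, beta=1.0, seed=12)
        t, e = table.outcomes()
        s = table.df["x"].to_numpy()
        grid = np.linspace(12, 100, 12)
        aucs, iauc = time_dependent_auc(s, t, e, grid)
        y = Surv.from_arrays(event=e.astype(bool), time=t)
        ref_aucs, _ = cumulative_dynamic_auc(y, y, s, grid)
        np.testing.assert_allclose(aucs, ref_aucs, atol=1e-10)
        # iAUC with the same event-density weights over the reference curve
        from lifelines import KaplanMeierFitter

        km = KaplanMeierFitter().fit(t, e)
        F = 1.0 - km.survival_function_at_times(grid).to_numpy(float)
        dF = np.diff(np.concatenate([[0.0], F]))
        ref_iauc = float(np.sum(ref_aucs * dF / dF.sum()))
        assert iauc == pytest.approx(ref_iauc, abs=0.03)

    def test_grid_outside_followup_rejected(self):
        table = _ph_cohort(n=100, seed=13)
        t, e = table.outcomes()
        with pytest.raises(EvaluationError):
            time_dependent_auc(t, t, e, np.array([t.max() + 10.0]))


class TestConcordance:
    def test_perfect_ordering(self):
        t = np.arange(1.0, 21.0)
        e = np.ones(20, int)
        c, lo, hi = concordance_index(-t, t, e, bootstrap_reps=0)
        assert c == 1.0

    def test_matches_exhaustive_enumeration_n10(self):
        rng = np.random.default_rng(14)
        t = rng.exponential(1.0, 10)
        e = rng.integers(0, 2, 10)
        e[0] = 1
        s = rng.standard_normal(10)
        c, *_ = concordance_index(s, t, e, bootstrap_reps=0)
        num = den = 0.0
        for i in range(10):
            for j in range(10):
                if t[i] < t[j] and e[i] == 1:
                    den += 1
                    num += 1.0 if s[i] > s[j] else (0.5 if s[i] == s[j] else 0.0)
        assert c == pytest.approx(num / den, rel=1e-12)

    def test_no_events_rejected(self):
        with pytest.raises(EvaluationError):
            concordance_index(np.arange(5.0), np.arange(5.0) + 1, np.zeros(5, int))


class TestNomogramAndCurves:
    def test_binary_covariate_points(self):
        table = _ph_cohort(n=600, beta=1.0, seed=15)
        df = table.df.copy()
        df["b"] = (df["x"] > 0).astype(float)
        spec, _ = build_nomogram(df, ("b",), bootstrap_reps=0)
        assert sorted(spec.point_maps["b"]["points"].tolist()) == [0.0, 100.0]

    def test_survival_monotone_in_points(self):
        table = simulate_cohort(CohortSimParams(
            n_patients=800, beta={"x1": 0.8, "x2": -0.5}, features=("x1", "x2"),
            censoring_target=0.3, admin_horizon_months=240.0,
            include_clinical=False, include_tacs=False, seed=16))
        spec, _ = build_nomogram(table.df, ("x1", "x2"), bootstrap_reps=0)
        for h in spec.horizons:
            col = f"survival_{int(h)}m"
            assert np.all(np.diff(spec.total_points_map[col]) <= 1e-12)
        assert max(m["points"].max() for m in spec.point_maps.values()) == pytest.approx(100.0)

    def test_calibration_of_correct_model(self):
        table = _ph_cohort(n=1000, beta=0.8, seed=17)
        _, cal = build_nomogram(table.df, ("x",), bootstrap_reps=30, seed=0)
        assert cal.mean_abs_error <= 0.05

    def test_score_curve_matches_km_by_decile(self):
        table = _ph_cohort(n=2000, beta=1.0, seed=18)
        t, e = table.outcomes()
        s = table.df["x"].to_numpy()
        deciles = np.quantile(s, np.linspace(0.05, 0.95, 10))
        curve = score_to_dfs_curve(deciles, s, t, e, horizon=60.0)
        assert np.all(np.diff(curve["dfs_probability"]) < 0)
        from lifelines import KaplanMeierFitter

        edges = np.quantile(s, np.linspace(0, 1, 11))
        for k in (2, 5, 8):  # interior deciles have enough patients
            in_bin = (s >= edges[k]) & (s < edges[k + 1])
            km = KaplanMeierFitter().fit(t[in_bin], e[in_bin])
            observed = float(km.survival_function_at_times([60.0]).iloc[0])
            predicted = float(curve["dfs_probability"].iloc[k])
            assert predicted == pytest.approx(observed, abs=0.07)


class TestSubgroups:
    def test_constant_grouping_equals_full_cohort(self):
        table = _ph_cohort(n=400, beta=1.0, seed=19)
        df = table.df.copy()
        df["g"] = "all"
        df["score"] = df["x"]
        t, e = table.outcomes()
        cut = float(np.median(df["score"]))
        rep = subgroup_report(df, ("g",), ("score",), {"score": cut})
        assert len(rep) == 1
        full = stratify_and_km(df["score"].to_numpy(), cut, t, e)
        assert rep.iloc[0]["hr"] == pytest.approx(full.hazard_ratio)

    def test_effect_only_in_one_subgroup(self):
        wins = 0
        for rep_i in range(15):
            rng = np.random.default_rng(2000 + rep_i)
            n = 600
            sub = rng.integers(0, 2, n)  # 1 = subgroup A with effect
            x = rng.standard_normal(n)
            eta = np.where(sub == 1, 1.2 * x, 0.0)
            t = 91.0 * (rng.exponential(1.0, n) * np.exp(-eta)) ** (1 / 1.5)
            df = pd.DataFrame({"sub": np.where(sub == 1, "A", "B"),
                               "score": x, "dfs_months": t, "event": 1})
            rep = subgroup_report(df, ("sub",), ("score",), {"score": 0.0})
            hr = rep.set_index("level")["hr"]
            wins += hr["A"] > hr["B"]
        assert wins >= 13

    def test_row_order_invariance(self):
        table = _ph_cohort(n=300, beta=1.0, seed=20)
        df = table.df.copy()
        df["g"] = np.where(df["x"] > 0, "hi", "lo")
        df["score"] = df["x"]
        rep1 = subgroup_report(df, ("g",), ("score",), {"score": 0.0})
        shuffled = df.sample(frac=1.0, random_state=3).reset_index(drop=True)
        rep2 = subgroup_report(shuffled, ("g",), ("score",), {"score": 0.0})
        key = lambda r: r.sort_values("level").reset_index(drop=True)
        pd.testing.assert_frame_equal(key(rep1), key(rep2))
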