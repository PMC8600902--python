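import numpy as np
import pandas as pd
import pytest

from fiberscore import (
    CohortSimParams,
    combine_scores,
    concordance_index,
    fit_cli_cox,
    fit_lasso_cox,
    fit_ridge_cox,
    simulate_cohort,
)
from fiberscore.scoring import (
    efron_partial_loglik,
    fit_tacs_score,
    lasso_path_n_selected,
)


def _feature_cohort(n=300, beta=None, seed=0, p=30, censoring=0.2):
    feats = tuple(f"f{i}" for i in range(p))
    beta = beta or {"f0": 1.0}
    return simulate_cohort(CohortSimParams(
        n_patients=n, beta=beta, features=feats, censoring_target=censoring,
        admin_horizon_months=240.0, include_clinical=False, include_tacs=False,
        seed=seed)), feats


class TestLassoCox:
    def test_huge_penalty_empty_model(self):
        table, feats = _feature_cohort(seed=1)
        t, e = table.outcomes()
        with pytest.warns(UserWarning, match="no features"):
            m = fit_lasso_cox(table.df[list(feats)], t, e, cv_folds=3,
                              lambda_grid=np.array([1e6]), seed=1)
        assert m.is_empty
        assert np.all(m.score(table.df) == 0)

    def test_score_is_dot_product(self):
        table, feats = _feature_cohort(seed=2)
        t, e = table.outcomes()
        m = fit_lasso_cox(table.df[list(feats)], t, e, cv_folds=3,
                          lambda_rule="min", seed=2)
        expected = table.df[list(m.feature_names)].to_numpy() @ m.coefficients
        np.testing.assert_allclose(m.score(table.df), expected, rtol=1e-12)

    def test_seeded_determinism(self):
        table, feats = _feature_cohort(seed=3)
        t, e = table.outcomes()
        a = fit_lasso_cox(table.df[list(feats)], t, e, cv_folds=3, seed=9)
        b = fit_lasso_cox(table.df[list(feats)], t, e, cv_folds=3, seed=9)
        assert a.feature_names == b.feature_names
        np.testing.assert_array_equal(a.coefficients, b.coefficients)

    def test_path_selection_monotone_in_penalty(self):
        table, feats = _feature_cohort(seed=4, beta={"f0": 1.0, "f1": -0.8})
        t, e = table.outcomes()
        alphas, n_sel = lasso_path_n_selected(table.df[list(feats)], t, e)
        # alphas descend, so selection counts must be non-decreasing
        assert np.all(np.diff(n_sel) >= 0)

    def test_too_few_events_rejected(self):
        table, feats = _feature_cohort(seed=5)
        df = table.df.copy()
        df["event"] = 0
        df.loc[0, "event"] = 1
        with pytest.raises(Exception):
            fit_lasso_cox(df[list(feats)], df["dfs_months"].to_numpy(),
                          df["event"].to_numpy(), cv_folds=3, seed=0)


class TestRidgeCox:
    def test_all_zero_indicator_patient_scores_zero(self):
        table = simulate_cohort(CohortSimParams(
            n_patients=300, beta={"tacs_2": 0.8}, censoring_target=0.3,
            admin_horizon_months=240.0, seed=6))
        t, e = table.outcomes()
        m = fit_tacs_score(table.df, t, e, cv_folds=3, seed=6)
        zero_patient = pd.DataFrame({f"tacs_{i}": [0] for i in range(1, 9)})
        assert m.score(zero_patient)[0] == 0.0
        assert len(m.coefficients) == 8  # ridge keeps everything

    def test_infinite_penalty_shrinks_to_zero(self):
        table = simulate_cohort(CohortSimParams(
            n_patients=200, beta={"tacs_1": 1.0}, censoring_target=0.3,
            admin_horizon_months=240.0, seed=7))
        t, e = table.outcomes()
        cols = [f"tacs_{i}" for i in range(1, 9)]
        m = fit_ridge_cox(table.df[cols], t, e, penalty=1e8)
        assert np.abs(m.coefficients).max() < 1e-4

    def test_risk_carrying_indicator_dominates(self):
        hits = 0
        for rep in range(20):
            table = simulate_cohort(CohortSimParams(
                n_patients=500, beta={"tacs_3": 1.0}, censoring_target=0.3,
                admin_horizon_months=240.0, seed=700 + rep))
            t, e = table.outcomes()
            m = fit_tacs_score(table.df, t, e, penalty=0.1)
            hits += int(np.argmax(m.coefficients)) == 2
        assert hits >= 18

    def test_constant_column_flagged(self):
        table = simulate_cohort(CohortSimParams(
            n_patients=200, beta={"tacs_1": 0.5}, censoring_target=0.3,
            admin_horizon_months=240.0, seed=8))
        df = table.df.copy()
        df["tacs_8"] = 0
        t = df["dfs_months"].to_numpy()
        e = df["event"].to_numpy()
        with pytest.warns(UserWarning, match="constant"):
            fit_ridge_cox(df[[f"tacs_{i}" for i in range(1, 9)]], t, e, penalty=1.0)


class TestClinicalCox:
    def test_nodal_only_risk_dominates(self):
        table = simulate_cohort(CohortSimParams(
            n_patients=800, beta={"nodal_status:N>=4": 1.2},
            censoring_target=0.3, admin_horizon_months=240.0, seed=9))
        t, e = table.outcomes()
        m = fit_cli_cox(table.df, t, e)
        coefs = dict(zip(m.feature_names, m.coefficients))
        target = coefs["nodal_status:N>=4"]
        others = [abs(v) for k, v in coefs.items() if not k.startswith("nodal")]
        assert target > max(others)

    def test_row_order_invariance(self):
        table = simulate_cohort(CohortSimParams(
            n_patients=300, beta={"grade:G3": 0.8}, censoring_target=0.3,
            admin_horizon_months=240.0, seed=10))
        t, e = table.outcomes()
        m1 = fit_cli_cox(table.df, t, e)
        shuffled = table.df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        m2 = fit_cli_cox(shuffled, shuffled["dfs_months"].to_numpy(),
                         shuffled["event"].to_numpy())
        s1 = pd.Series(m1.score(table.df), index=table.df["patient_id"])
        s2 = pd.Series(m2.score(shuffled), index=shuffled["patient_id"])
        np.testing.assert_allclose(s1.sort_index(), s2.sort_index(), rtol=1e-6)


class TestCombination:
    def test_single_component_rank_identical(self):
        table, _ = _feature_cohort(n=400, beta={"f0": 1.0}, seed=11, p=2)
        df = table.df.copy()
        df["s1"] = df["f0"]
        t, e = table.outcomes()
        m = combine_scores(df, ("s1",), t, e)
        combined = m.score(df)
        c1, *_ = concordance_index(combined, t, e, bootstrap_reps=0)
        c2, *_ = concordance_index(df["s1"].to_numpy(), t, e, bootstrap_reps=0)
        assert c1 == pytest.approx(c2)

    def test_noise_component_weight_near_zero(self):
        table = simulate_cohort(CohortSimParams(
            n_patients=2000, beta={"s1": 1.0}, features=("s1", "noise"),
            censoring_target=0.3, admin_horizon_months=240.0,
            include_clinical=False, include_tacs=False, seed=12))
        t, e = table.outcomes()
        m = combine_scores(table.df, ("s1", "noise"), t, e)
        w = dict(zip(m.feature_names, m.coefficients))
        assert abs(w["noise"]) < 0.1

    def test_collinear_components_flagged(self):
        table, _ = _feature_cohort(n=200, seed=13, p=2)
        df = table.df.copy()
        df["s1"] = df["f0"]
        df["s2"] = 2.0 * df["f0"]
        t, e = table.outcomes()
        with pytest.warns(UserWarning, match="collinear"):
            try:
                combine_scores(df, ("s1", "s2"), t, e)
            except Exception:
                pass


class TestEfronLoglik:
    def test_matches_lifelines_at_fitted_beta(self):
        from lifelines import CoxPHFitter

        t = np.array([1.0, 2, 3, 4, 5, 6])
        e = np.array([1, 1, 0, 1, 0, 1])
        x = np.array([0.5, -1.0, 2.0, 0.0, 1.5, -0.5])
        df = pd.DataFrame({"x": x, "dfs_months": t, "event": e})
        cph = CoxPHFitter().fit(df, "dfs_months", "event")
        beta = float(cph.params_.iloc[0])
        assert efron_partial_loglik(beta * x, t, e) == pytest.approx(
            cph.log_likelihood_, rel=1e-9
        )

    def test_handles_ties(self):
        t = np.array([2.0, 2.0, 2.0, 5.0, 5.0, 8.0])
        e = np.array([1, 1, 0, 1, 1, 1])
        x = np.array([1.0, 0.0, -1.0, 0.5, -0.5, 0.0])
        from lifelines import CoxPHFitter

        df = pd.DataFrame({"x": x, "dfs_months": t, "event": e})
        cph = CoxPHFitter().fit(df, "dfs_months", "event")
        beta = float(cph.params_.iloc[0])
        assert efron_partial_loglik(beta * x, t, e) == pytest.approx(
            cph.log_likelihood_, rel=1e-9
        )


class TestScoreInvariances:
    def test_constant_shift_leaves_rank_metrics_unchanged(self):
        table, feats = _feature_cohort(n=400, seed=14)
        t, e = table.outcomes()
        s = table.df["f0"].to_numpy()
        from fiberscore import roc_at_horizon

        a = roc_at_horizon(s, t, e, horizon=60, bootstrap_reps=0)
        b = roc_at_horizon(s + 100.0, t, e, horizon=60, bootstrap_reps=0)
        assert a.auc == pytest.approx(b.auc, abs=1e-12)
        ca, *_ = concordance_index(s, t, e, bootstrap_reps=0)
        cb, *_ = concordance_index(s + 100.0, t, e, bootstrap_reps=0)
        assert ca == cb

    def test_sign_recovery_on_ph_data(self):
        hits = 0
        reps = 20
        for rep in range(reps):
            table, feats = _feature_cohort(
                n=1000, beta={"f0": 1.0, "f1": -1.0}, seed=1500 + rep, p=10)
            t, e = table.outcomes()
            m = fit_lasso_cox(table.df[list(feats)], t, e, cv_folds=3,
                              lambda_rule="min", seed=rep)
            co = dict(zip(m.feature_names, m.coefficients))
            ok = co.get("f0", 0) > 0 and co.get("f1", 0) < 0
            hits += ok
        assert hits / reps >= 0.95
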