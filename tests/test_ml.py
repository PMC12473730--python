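import numpy as np
import pandas as pd
import pytest

from neuromusc import ml


@pytest.fixture(scope="module")
def table(model, default_experiment):
    msets = default_experiment["metric_sets"]
    y = ml.make_target(msets, noise_frac=0.10, seed=2024)
    df = ml.build_feature_table(default_experiment["trials"], model,
                                metric_sets=msets, target=y)
    df = ml.split_dataset(df, seed=2024)
    return ml.standardize_features(df)


class TestFeatureTable:
    def test_row_count_matches_trials(self, table):
        assert len(table.frame) == 70

    def test_training_rows_standardized(self, table):
        tr = table.rows("train")[table.feature_cols]
        assert np.abs(tr.mean().to_numpy()).max() < 1e-9
        assert np.abs(tr.std(ddof=0).to_numpy() - 1).max() < 1e-9

    def test_too_few_trials_rejected(self, model, default_experiment):
        with pytest.raises(ValueError):
            ml.build_feature_table(default_experiment["trials"][:10], model)

    def test_pca_block_threshold(self, table):
        t2 = ml.pca_block(table, variance=0.95)
        evr = t2.pca_.explained_variance_ratio_
        assert evr.sum() >= 0.95
        assert evr[:-1].sum() < 0.95


class TestSplit:
    def test_exact_ratios_on_round_strata(self, rng):
        df = pd.DataFrame({"task": np.repeat(list("abcde"), 20),
                           "load": 0.0, "x": rng.random(100)})
        out = ml.split_dataset(df, seed=1)
        counts = out["split"].value_counts()
        assert counts["train"] == 70
        assert counts["val"] == 15
        assert counts["test"] == 15

    def test_deterministic(self, table, model, default_experiment):
        msets = default_experiment["metric_sets"]
        df = ml.build_feature_table(default_experiment["trials"], model,
                                    metric_sets=msets)
        a = ml.split_dataset(df, seed=7)["split"]
        b = ml.split_dataset(df, seed=7)["split"]
        assert (a == b).all()

    def test_stratum_proportions_within_one_trial(self, table):
        df = table.frame
        for task, grp in df.groupby("task"):
            frac = (grp["split"] == "train").mean()
            n = len(grp)
            assert 0.70 - 1.0 / n <= frac <= 0.70 + 1.0 / n

    def test_small_stratum_rejected(self):
        df = pd.DataFrame({"task": ["a", "a", "b"], "load": 0.0,
                           "x": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="stratum"):
            ml.split_dataset(df)

    def test_splits_disjoint_and_exhaustive(self, table):
        assert set(table.frame["split"]) == {"train", "val", "test"}
        assert table.frame["split"].notna().all()


class TestTuning:
    def test_tie_break_prefers_lower_sd(self):
        cv_results = {"mean_test_score": np.array([-1.0, -1.0, -1.2]),
                      "std_test_score": np.array([0.20, 0.10, 0.01])}
        assert ml._refit_lower_sd(cv_results) == 1

    def test_planted_noiseless_linear_recovery(self, rng):
        n = 80
        X = rng.normal(size=(n, 5))
        y = 3.0 * X[:, 0] - 2.0 * X[:, 1]
        df = pd.DataFrame(X, columns=[f"f{i}" for i in range(5)])
        df["task"] = np.repeat(["a", "b"], n // 2)
        df["load"] = 0.0
        df["target"] = y
        df = ml.split_dataset(df, seed=2024)
        table = ml.standardize_features(df)
        rep = ml.tune_and_fit(ml.ModelSpec("elastic_net", budget=25,
                                           seed=2024), table)
        assert rep.cv_metrics["r2"][0] > 0.99
        assert rep.test_metrics["r2"] > 0.99

    def test_seeded_rerun_is_identical(self, table):
        spec = ml.ModelSpec("elastic_net", budget=10, seed=2024)
        a = ml.tune_and_fit(spec, table)
        b = ml.tune_and_fit(spec, table)
        assert a.best_params == b.best_params
        assert a.cv_metrics == b.cv_metrics

    def test_no_leakage_from_test_rows(self, model, default_experiment):
        """Deleting the test rows before tuning changes nothing about the
        selected hyperparameters."""
        msets = default_experiment["metric_sets"]
        y = ml.make_target(msets, seed=2024)
        df = ml.build_feature_table(default_experiment["trials"], model,
                                    metric_sets=msets, target=y)
        df = ml.split_dataset(df, seed=2024)
        full = ml.standardize_features(df)
        pruned = ml.standardize_features(
            df[df["split"] != "test"].reset_index(drop=True))
        spec = ml.ModelSpec("elastic_net", budget=8, seed=2024)
        a = ml.tune_and_fit(spec, full)
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            # re-tune on the pruned table; compare selections only
            from sklearn.model_selection import KFold, RandomizedSearchCV
            est = ml.build_estimator("elastic_net", seed=2024)
            space = ml._default_space("elastic_net", "random")
            cv = KFold(5, shuffle=True, random_state=2024)
            s = RandomizedSearchCV(est, space, n_iter=8, cv=cv,
                                   scoring="neg_mean_absolute_error",
                                   refit=ml._refit_lower_sd,
                                   random_state=2024)
            Xp, yp = pruned.xy("train")
            s.fit(Xp, yp)
        assert a.best_params == s.best_params_

    def test_grid_dialect(self, table):
        rep = ml.tune_and_fit(ml.ModelSpec("elastic_net", tuning="grid",
                                           seed=2024), table)
        assert rep.test_metrics["rmse"] >= rep.test_metrics["mae"]


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.array([1.0, 2.0, 3.0])
        out = ml.evaluate(y, y)
        assert out == {"mae": 0.0, "rmse": 0.0, "r2": 1.0}

    def test_constant_predictor_r2_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        out = ml.evaluate(y, np.full_like(y, y.mean()))
        assert out["r2"] == pytest.approx(0.0)

    def test_alternating_unit_errors(self):
        y = np.arange(10, dtype=float)
        pred = y + np.where(np.arange(10) % 2 == 0, 1.0, -1.0)
        out = ml.evaluate(y, pred)
        assert out["mae"] == pytest.approx(1.0)
        assert out["rmse"] == pytest.approx(1.0)

    def test_rmse_at_least_mae(self, rng):
        for _ in range(20):
            y = rng.normal(size=30)
            p = y + rng.normal(scale=rng.uniform(0.1, 2), size=30)
            out = ml.evaluate(y, p)
            assert out["rmse"] >= out["mae"] - 1e-12

    def test_empty_split_rejected(self):
        with pytest.raises(ValueError):
            ml.evaluate([], [])


class TestImportance:
    @pytest.fixture(scope="class")
    def planted(self):
        n = 150
        X = np.random.default_rng(8).normal(size=(n, 6))
        y = 3.0 * X[:, 0] + 0.1 * np.random.default_rng(9).normal(size=n)
        df = pd.DataFrame(X, columns=[f"f{i}" for i in range(6)])
        df["task"] = np.repeat(["a", "b"], n // 2)
        df["load"] = 0.0
        df["target"] = y
        df = ml.split_dataset(df, seed=2024)
        return ml.standardize_features(df)

    def test_raw_fold_importances_sum_to_100(self, planted):
        from sklearn.ensemble import RandomForestRegressor
        X, y = planted.xy("train")
        rf = RandomForestRegressor(n_estimators=50, random_state=0)
        rf.fit(X, y)
        imp = rf.feature_importances_
        norm = 100 * imp / imp.sum()
        assert norm.sum() == pytest.approx(100.0, abs=1e-6)

    def test_impurity_normalized_to_100(self, planted):
        imp, _ = ml.feature_importance(planted, B=50, seed=1)
        # fold medians need not sum to 100, but every fold's raw vector
        # did; the median of per-fold sums is preserved for the top block
        assert imp["impurity_median"].max() > 50.0
        assert (imp["ci_lo"] <= imp["impurity_median"]).all()
        assert (imp["impurity_median"] <= imp["ci_hi"]).all()

    def test_planted_feature_ranked_first_by_both_methods(self, planted):
        hits_imp = hits_perm = 0
        runs = 8
        for k in range(runs):
            imp, perm = ml.feature_importance(planted, B=30, seed=100 + k)
            hits_imp += imp.iloc[0]["feature"] == "f0"
            hits_perm += perm.iloc[0]["feature"] == "f0"
        assert hits_imp == runs
        assert hits_perm == runs

    def test_null_feature_permutation_near_zero(self, planted):
        _, perm = ml.feature_importance(planted, B=30, seed=5)
        row = perm[perm["feature"] == "f5"].iloc[0]
        assert abs(row["perm_mean"]) <= 2 * max(row["perm_sd"], 1e-9) + 0.05

    def test_non_tree_family_refuses_impurity(self, planted):
        imp, perm = ml.feature_importance(planted, family="elastic_net",
                                          B=30, seed=2)
        assert imp is None
        assert perm is not None


class TestDiagnostics:
    def test_perfect_predictions_calibrate_exactly(self, rng):
        y = rng.normal(size=40)
        d = ml.residual_diagnostics(y, y)
        assert d["calibration_intercept"] == pytest.approx(0.0, abs=1e-9)
        assert d["calibration_slope"] == pytest.approx(1.0, rel=1e-9)
        assert len(d["decile_table"]) == 10
        assert np.abs(d["decile_table"]["bias"]).max() < 1e-12

    def test_homoscedastic_noise_uncorrelated(self):
        rng = np.random.default_rng(0)
        pred = rng.normal(size=200)
        y = pred + rng.normal(scale=0.5, size=200)
        d = ml.residual_diagnostics(y, pred)
        assert abs(d["spearman_abs_err_vs_pred"]) < 0.2

    def test_heteroscedastic_noise_detected(self):
        hits = 0
        runs = 20
        for k in range(runs):
            rng = np.random.default_rng(k)
            pred = rng.uniform(1, 5, 500)
            y = pred + rng.normal(scale=0.3 * pred)
            d = ml.residual_diagnostics(y, pred)
            hits += d["breusch_pagan_p"] < 0.05
        assert hits >= 0.8 * runs

    def test_few_distinct_predictions_degrade_with_warning(self, rng):
        y = rng.normal(size=30)
        pred = np.round(y)   # few distinct values
        with pytest.warns(RuntimeWarning, match="distinct"):
            ml.residual_diagnostics(y, pred)

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(ValueError):
            ml.residual_diagnostics(rng.normal(size=5), rng.normal(size=5))

    def test_plot_files_emitted(self, rng, tmp_path):
        y = rng.normal(size=40)
        d = ml.residual_diagnostics(y, y + rng.normal(scale=0.2, size=40),
                                    out_dir=tmp_path)
        for p in d["plots"]:
            assert (tmp_path / p.split("/")[-1]).exists()


class TestCombinedScenarios:
    def test_pair_predictions_are_emitted_and_bounded(self, table):
        rep = ml.tune_and_fit(ml.ModelSpec("elastic_net", budget=5,
                                           seed=2024), table)
        out = ml.predict_combined(rep, table,
                                  [("back_squat", "DJ50"),
                                   ("deadlift", "CMJ")])
        assert list(out["pair"]) == ["back_squat+DJ50", "deadlift+CMJ"]
        assert (out["status"] == "hypothesis-generating").all()
        y = table.frame["target"]
        span = y.max() - y.min()
        assert out["predicted_score"].between(y.min() - span,
                                              y.max() + span).all()

    def test_unknown_task_rejected(self, table):
        rep = ml.tune_and_fit(ml.ModelSpec("elastic_net", budget=3,
                                           seed=2024), table)
        with pytest.raises(ValueError, match="unknown task"):
            ml.predict_combined(rep, table, [("back_squat", "yoga")])
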