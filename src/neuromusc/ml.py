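"""Feature-table construction, model tuning, evaluation, importance and
residual diagnostics for the prediction layer.

Trials are summarized into one feature row each (time-normalized waveform
summaries plus derived metrics), standardized with training-set
statistics, and split 70/15/15 with task x load stratification. Models
(elastic net, RBF-kernel SVR, random forest, gradient boosting, and a
multilayer-perceptron network) are tuned by randomized search (or the
grid dialect) with 5-fold cross-validation scored by mean absolute error,
ties broken by the lower across-fold SD. Feature scaling (and optional
PCA) live inside the model pipeline, so they are re-fitted within each
training fold only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import clone
from sklearn.decomposition import PCA
from sklearn.ensemble import HistGradientBoostingRegressor, RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.linear_model import ElasticNet
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score
from sklearn.model_selection import (GridSearchCV, KFold, RandomizedSearchCV,
                                     cross_validate, train_test_split)
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .body import JOINTS
from .metrics import adaptation_proxies, peak_metrics

__all__ = [
    "FeatureTable", "ModelSpec", "FitReport", "build_feature_table",
    "make_target", "split_dataset", "build_estimator", "tune_and_fit",
    "evaluate", "feature_importance", "predict_combined",
    "residual_diagnostics",
    "MODEL_FAMILIES", "DEFAULT_SEED",
]

DEFAULT_SEED = 2024
MODEL_FAMILIES = ("elastic_net", "svr_rbf", "random_forest",
                  "gradient_boosting", "ann")
META_COLS = ("task", "replicate", "load", "split", "target")


@dataclass
class FeatureTable:
    """Trials x standardized features with target and split labels."""

    frame: pd.DataFrame
    feature_cols: list[str]
    target_col: str = "target"
    scaler_mean: pd.Series | None = None
    scaler_sd: pd.Series | None = None

    def rows(self, split: str):
        return self.frame[self.frame["split"] == split]

    def xy(self, split: str | None = None):
        df = self.frame if split is None else self.rows(split)
        return (df[self.feature_cols].to_numpy(dtype=float),
                df[self.target_col].to_numpy(dtype=float))


@dataclass
class ModelSpec:
    family: str
    search_space: dict | None = None       # default per family
    budget: int = 200                      # randomized-search trials
    folds: int = 5
    tuning: str = "random"                 # 'random' | 'grid'
    seed: int = DEFAULT_SEED
    pca_variance: float | None = None      # e.g. 0.95 to enable PCA

    def __post_init__(self):
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")


@dataclass
class FitReport:
    family: str
    best_params: dict
    cv_metrics: dict                       # metric -> (mean, sd)
    test_metrics: dict
    importance: pd.DataFrame | None = None
    permutation: pd.DataFrame | None = None
    diagnostics: dict = field(default_factory=dict)
    seed: int = DEFAULT_SEED
    estimator: object = None


# ---------------------------------------------------------------------------
# feature construction


def _waveform_summaries(trial, model) -> dict:
    """Peak / mean / integral of time-normalized stance waveforms."""
    out = {}
    c = trial.contact
    t = trial.t
    xi = np.linspace(0, 1, 101)

    def norm(w):
        wc = w[c]
        return np.interp(xi, np.linspace(0, 1, len(wc)), wc)

    for j, joint in enumerate(JOINTS):
        w = norm(trial.tau[:, j])
        out[f"mom_{joint}_peak"] = float(w.max())
        out[f"mom_{joint}_mean"] = float(w.mean())
        out[f"mom_{joint}_integral"] = float(np.trapezoid(w, xi))
    for k, comp in ((1, "v"), (0, "ap")):
        w = norm(trial.grf[:, k])
        out[f"grf_{comp}_peak"] = float(w.max())
        out[f"grf_{comp}_mean"] = float(w.mean())
        out[f"grf_{comp}_integral"] = float(np.trapezoid(w, xi))
    for i, name in enumerate(model.muscle_names):
        w = norm(trial.activations[:, i])
        out[f"act_{name}_peak"] = float(w.max())
        out[f"act_{name}_mean"] = float(w.mean())
    return out


def build_feature_table(trials, model, metric_sets=None,
                        target=None) -> pd.DataFrame:
    """One raw (unstandardized) feature row per solved trial.

    ``metric_sets`` are computed if not given; ``target`` may be a vector
    aligned with ``trials``. Standardization happens after splitting (see
    :func:`split_dataset` / :func:`standardize_features`).
    """
    trials = list(trials)
    if len(trials) < 20 or len({t.task.name for t in trials}) < 2:
        raise ValueError("need >= 20 trials spanning >= 2 tasks")
    if metric_sets is None:
        metric_sets = [peak_metrics(t, model) for t in trials]
    rows = []
    for trial, ms in zip(trials, metric_sets):
        row = {"task": trial.task.name, "replicate": trial.replicate,
               "load": trial.load_fraction}
        row.update(ms.scalar_fields())
        row.update(_waveform_summaries(trial, model))
        rows.append(row)
    df = pd.DataFrame(rows)
    df = df.drop(columns=[c for c in df.columns
                          if df[c].dtype != object and df[c].isna().any()])
    if target is not None:
        df["target"] = np.asarray(target, dtype=float)
    return df


def make_target(metric_sets, noise_frac: float = 0.10,
                seed: int = DEFAULT_SEED) -> np.ndarray:
    """Composite adaptation score: the mean of the four z-scored
    adaptation proxies, plus Gaussian noise with SD equal to
    ``noise_frac`` of the signal SD."""
    proxies = adaptation_proxies(metric_sets)
    y = np.array([p.composite for p in proxies])
    rng = np.random.default_rng(seed)
    return y + rng.standard_normal(len(y)) * noise_frac * y.std(ddof=0)


def split_dataset(df: pd.DataFrame, ratios=(0.70, 0.15, 0.15),
                  strata=("task", "load"), seed: int = DEFAULT_SEED
                  ) -> pd.DataFrame:
    """Disjoint train/val/test labels at the given ratios, stratified so
    each task x load cell keeps its proportions within rounding."""
    if not np.isclose(sum(ratios), 1.0):
        raise ValueError("ratios must sum to 1")
    rng = np.random.default_rng(seed)
    df = df.copy()
    key = df[list(strata)].astype(str).agg("|".join, axis=1)
    labels = np.empty(len(df), dtype=object)
    for s_idx, cell in enumerate(key.unique()):
        idx = np.flatnonzero(key == cell)
        if len(idx) < 3:
            raise ValueError(f"stratum {cell!r} has fewer than 3 rows")
        idx = idx[rng.permutation(len(idx))]
        n = len(idx)
        n_tr = int(round(ratios[0] * n))
        rem = n - n_tr
        # alternate which of val/test receives the odd row, so the global
        # proportions stay balanced across strata
        n_va = rem // 2 + (rem % 2 if s_idx % 2 == 0 else 0)
        labels[idx[:n_tr]] = "train"
        labels[idx[n_tr:n_tr + n_va]] = "val"
        labels[idx[n_tr + n_va:]] = "test"
    df["split"] = labels
    return df


def standardize_features(df: pd.DataFrame) -> FeatureTable:
    """z-score every feature column using training-row statistics only."""
    feature_cols = [c for c in df.columns if c not in META_COLS]
    train = df[df["split"] == "train"]
    mean = train[feature_cols].mean()
    sd = train[feature_cols].std(ddof=0).replace(0.0, 1.0)
    out = df.copy()
    out[feature_cols] = (df[feature_cols] - mean) / sd
    return FeatureTable(frame=out, feature_cols=feature_cols,
                        scaler_mean=mean, scaler_sd=sd)


def pca_block(table: FeatureTable, variance: float = 0.95) -> FeatureTable:
    """Append principal-component columns retaining the smallest count
    reaching the variance threshold (fitted on training rows)."""
    X_tr = table.rows("train")[table.feature_cols].to_numpy(dtype=float)
    pca = PCA(n_components=variance, svd_solver="full")
    pca.fit(X_tr)
    Z = pca.transform(table.frame[table.feature_cols].to_numpy(dtype=float))
    frame = table.frame.copy()
    pc_cols = [f"pc_{i + 1}" for i in range(Z.shape[1])]
    for i, cname in enumerate(pc_cols):
        frame[cname] = Z[:, i]
    t = FeatureTable(frame=frame, feature_cols=table.feature_cols + pc_cols,
                     scaler_mean=table.scaler_mean, scaler_sd=table.scaler_sd)
    t.pca_ = pca
    return t


# ---------------------------------------------------------------------------
# models


def _default_space(family: str, tuning: str) -> dict:
    if tuning == "grid":
        # the compact grid dialect: learning rates, hidden units, trees
        return {
            "elastic_net": {"model__alpha": [1e-3, 1e-2, 1e-1, 1.0],
                            "model__l1_ratio": [0.2, 0.5, 0.8]},
            "svr_rbf": {"model__C": [1.0, 10.0, 100.0],
                        "model__gamma": ["scale", 0.01, 0.1]},
            "random_forest": {"model__n_estimators": [50, 100, 150],
                              "model__min_samples_leaf": [1, 2, 4]},
            "gradient_boosting": {"model__learning_rate": [0.001, 0.005, 0.01],
                                  "model__max_iter": [50, 100, 150]},
            "ann": {"model__hidden_layer_sizes": [(32,) * 3, (64,) * 3,
                                                  (128,) * 3],
                    "model__learning_rate_init": [0.001, 0.005, 0.01]},
        }[family]
    return {
        "elastic_net": {"model__alpha": sps.loguniform(1e-4, 1e1),
                        "model__l1_ratio": sps.uniform(0.0, 1.0)},
        "svr_rbf": {"model__C": sps.loguniform(1e-1, 1e3),
                    "model__gamma": sps.loguniform(1e-3, 1e0),
                    "model__epsilon": sps.loguniform(1e-3, 3e-1)},
        "random_forest": {"model__n_estimators": [50, 100, 150],
                          "model__max_depth": [None, 3, 5, 8],
                          "model__min_samples_leaf": [1, 2, 4],
                          "model__max_features": ["sqrt", 0.5, 1.0]},
        "gradient_boosting": {"model__learning_rate": sps.loguniform(1e-2, 3e-1),
                              "model__max_leaf_nodes": [7, 15, 31],
                              "model__max_depth": [None, 3, 6],
                              "model__l2_regularization": sps.loguniform(1e-8, 1e0)},
        "ann": {"model__hidden_layer_sizes": [(32,) * 3, (64,) * 3,
                                              (128,) * 3],
                "model__alpha": sps.loguniform(1e-5, 1e-1),
                "model__learning_rate_init": [0.001, 0.005, 0.01]},
    }[family]


def build_estimator(family: str, seed: int = DEFAULT_SEED,
                    pca_variance: float | None = None) -> Pipeline:
    """Scaler (+ optional PCA) + model pipeline; scaling/PCA refit within
    each training fold only (they live inside the pipeline)."""
    if family == "elastic_net":
        model = ElasticNet(max_iter=50_000, random_state=seed)
    elif family == "svr_rbf":
        model = SVR(kernel="rbf")
    elif family == "random_forest":
        model = RandomForestRegressor(n_estimators=100, random_state=seed)
    elif family == "gradient_boosting":
        model = HistGradientBoostingRegressor(
            early_stopping=True, validation_fraction=0.10,
            n_iter_no_change=50, random_state=seed)
    elif family == "ann":
        model = MLPRegressor(hidden_layer_sizes=(64, 64, 64),
                             activation="relu", solver="adam",
                             learning_rate_init=0.001, max_iter=800,
                             early_stopping=True, n_iter_no_change=20,
                             validation_fraction=0.15, random_state=seed)
    else:
        raise ValueError(f"unknown model family {family!r}")
    steps = [("scale", StandardScaler())]
    if pca_variance is not None:
        steps.append(("pca", PCA(n_components=pca_variance,
                                 svd_solver="full")))
    steps.append(("model", model))
    return Pipeline(steps)


def _refit_lower_sd(cv_results) -> int:
    """Best configuration: minimal mean CV MAE, ties broken by lower SD."""
    mean = -np.asarray(cv_results["mean_test_score"])
    sd = np.asarray(cv_results["std_test_score"])
    order = np.lexsort((sd, np.round(mean, 12)))
    return int(order[0])


def tune_and_fit(spec: ModelSpec, table: FeatureTable) -> FitReport:
    """Tune on the training split only, refit the best configuration, and
    evaluate on the held-out test split."""
    X_tr, y_tr = table.xy("train")
    est = build_estimator(spec.family, seed=spec.seed,
                          pca_variance=spec.pca_variance)
    space = spec.search_space or _default_space(spec.family, spec.tuning)
    cv = KFold(n_splits=spec.folds, shuffle=True, random_state=spec.seed)
    common = dict(scoring="neg_mean_absolute_error", cv=cv,
                  refit=_refit_lower_sd, n_jobs=1)
    if spec.tuning == "grid":
        search = GridSearchCV(est, space, **common)
    else:
        search = RandomizedSearchCV(est, space, n_iter=spec.budget,
                                    random_state=spec.seed, **common)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        search.fit(X_tr, y_tr)
        best = search.best_estimator_
        # per-fold CV metrics of the selected configuration
        cvres = cross_validate(clone(best), X_tr, y_tr, cv=cv, scoring={
            "mae": "neg_mean_absolute_error",
            "rmse": "neg_root_mean_squared_error", "r2": "r2"})
    cv_metrics = {
        "mae": (float(-cvres["test_mae"].mean()),
                float(cvres["test_mae"].std())),
        "rmse": (float(-cvres["test_rmse"].mean()),
                 float(cvres["test_rmse"].std())),
        "r2": (float(cvres["test_r2"].mean()), float(cvres["test_r2"].std())),
    }
    X_te, y_te = table.xy("test")
    test_metrics = evaluate(y_te, best.predict(X_te))
    return FitReport(family=spec.family,
                     best_params={k: v for k, v in search.best_params_.items()},
                     cv_metrics=cv_metrics, test_metrics=test_metrics,
                     seed=spec.seed, estimator=best)


def evaluate(y_true, y_pred) -> dict:
    """MAE, RMSE and R^2 (standard definitions; RMSE >= MAE always)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_true) == 0:
        raise ValueError("empty evaluation split")
    return {"mae": float(mean_absolute_error(y_true, y_pred)),
            "rmse": float(np.sqrt(mean_squared_error(y_true, y_pred))),
            "r2": float(r2_score(y_true, y_pred))}


def predict_combined(report: FitReport, table: FeatureTable,
                     pairs) -> pd.DataFrame:
    """Hypothesis-generating predictions for combined-training scenarios.

    A pair's feature vector is the element-wise mean of the two member
    tasks' median feature rows (a convex combination stays inside the
    training feature space, which concatenation would not); predictions
    are labeled hypothesis-generating because no combined-training trial
    exists in the data.
    """
    df = table.frame
    rows = []
    for a, b in pairs:
        va = df[df["task"] == a][table.feature_cols].median()
        vb = df[df["task"] == b][table.feature_cols].median()
        if va.isna().any() or vb.isna().any():
            raise ValueError(f"unknown task in pair ({a}, {b})")
        x = 0.5 * (va + vb)
        pred = float(report.estimator.predict(
            x.to_numpy(dtype=float)[None, :])[0])
        rows.append({"pair": f"{a}+{b}", "predicted_score": pred,
                     "status": "hypothesis-generating"})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# importance


def feature_importance(table: FeatureTable, family: str = "random_forest",
                       B: int = 200, folds: int = 5,
                       seed: int = DEFAULT_SEED, n_repeats: int = 10,
                       params: dict | None = None):
    """Impurity-based importances (tree ensembles) with fold medians,
    BCa confidence intervals over resampled folds, and permutation
    importance on a 20% in-fold validation split (10 repeats).

    Non-tree families refuse the impurity path; permutation importance
    still runs.
    """
    from .metrics import bca_interval     # local import to avoid cycle

    X_tr, y_tr = table.xy("train")
    cols = table.feature_cols
    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    is_tree = family in ("random_forest", "gradient_boosting")
    imp_folds = []
    perm_rows = []
    for k, (tr, _va) in enumerate(cv.split(X_tr)):
        est = build_estimator(family, seed=seed)
        if params:
            est.set_params(**params)
        Xf, yf = X_tr[tr], y_tr[tr]
        Xa, Xb, ya, yb = train_test_split(Xf, yf, test_size=0.20,
                                          random_state=seed + k)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(Xa, ya)
            if is_tree and hasattr(est["model"], "feature_importances_"):
                imp = est["model"].feature_importances_
                s = imp.sum()
                imp_folds.append(100 * imp / s if s > 0 else imp)
            pi = permutation_importance(est, Xb, yb, n_repeats=n_repeats,
                                        random_state=seed + k, n_jobs=1)
        perm_rows.append(pi.importances_mean)
    perm = pd.DataFrame({
        "feature": cols,
        "perm_mean": np.mean(perm_rows, axis=0),
        "perm_sd": np.std(perm_rows, axis=0)})
    if not imp_folds:
        return None, perm.sort_values("perm_mean", ascending=False)
    F = np.asarray(imp_folds)             # folds x features
    med = np.median(F, axis=0)
    rng_seed = seed
    lo = np.empty(len(cols))
    hi = np.empty(len(cols))
    for j in range(len(cols)):
        lo[j], hi[j] = bca_interval(F[:, j], np.median, B=B,
                                    seed=rng_seed + j)
    imp = pd.DataFrame({"feature": cols, "impurity_median": med,
                        "ci_lo": lo, "ci_hi": hi})
    imp = imp.sort_values("impurity_median", ascending=False)
    return imp.reset_index(drop=True), perm.sort_values(
        "perm_mean", ascending=False).reset_index(drop=True)


# ---------------------------------------------------------------------------
# diagnostics


def residual_diagnostics(y_true, y_pred, out_dir=None, prefix="model"):
    """Calibration intercept/slope, decile bias/MAE table, Spearman
    rho(|e|, yhat), Breusch-Pagan heteroscedasticity test; optional plot
    files (residual-vs-fitted with a LOESS smooth, standardized-residual
    Q-Q, calibration)."""
    import statsmodels.api as sm
    from statsmodels.stats.diagnostic import het_breuschpagan

    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_true) < 20:
        raise ValueError("need at least 20 evaluation rows")
    e = y_true - y_pred

    slope, intercept = np.polyfit(y_pred, y_true, 1)
    n_distinct = len(np.unique(np.round(y_pred, 12)))
    n_bins = 10
    if n_distinct < 10:
        warnings.warn("fewer than 10 distinct predictions: decile table "
                      "degrades to distinct-value bins", RuntimeWarning,
                      stacklevel=2)
        n_bins = n_distinct
    bins = pd.qcut(y_pred, q=n_bins, duplicates="drop")
    dec = pd.DataFrame({"bin": bins, "bias": e, "abs_err": np.abs(e)})
    decile_table = dec.groupby("bin", observed=True).agg(
        bias=("bias", "mean"), mae=("abs_err", "mean"),
        n=("bias", "size")).reset_index(drop=True)

    rho, rho_p = sps.spearmanr(np.abs(e), y_pred)
    exog = sm.add_constant(y_pred)
    bp_stat, bp_p, _, _ = het_breuschpagan(e, exog)

    diag = {"calibration_intercept": float(intercept),
            "calibration_slope": float(slope),
            "decile_table": decile_table,
            "spearman_abs_err_vs_pred": float(rho),
            "spearman_p": float(rho_p),
            "breusch_pagan_stat": float(bp_stat),
            "breusch_pagan_p": float(bp_p)}

    if out_dir is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        lo = sm.nonparametric.lowess(e, y_pred, frac=0.6)
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.scatter(y_pred, e, s=12, alpha=0.7)
        ax.plot(lo[:, 0], lo[:, 1], color="C1")
        ax.axhline(0, color="gray", lw=0.8)
        ax.set_xlabel("fitted"); ax.set_ylabel("residual")
        fig.tight_layout(); fig.savefig(out / f"{prefix}_resid_fitted.png")
        plt.close(fig)
        z = (e - e.mean()) / max(e.std(ddof=1), 1e-12)
        fig = sm.qqplot(z, line="45")
        fig.tight_layout(); fig.savefig(out / f"{prefix}_qq.png")
        plt.close(fig)
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.scatter(y_pred, y_true, s=12, alpha=0.7)
        lim = [min(y_pred.min(), y_true.min()), max(y_pred.max(), y_true.max())]
        ax.plot(lim, lim, color="gray", lw=0.8)
        ax.set_xlabel("predicted"); ax.set_ylabel("observed")
        fig.tight_layout(); fig.savefig(out / f"{prefix}_calibration.png")
        plt.close(fig)
        diag["plots"] = [str(out / f"{prefix}_resid_fitted.png"),
                         str(out / f"{prefix}_qq.png"),
                         str(out / f"{prefix}_calibration.png")]
    return diag
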