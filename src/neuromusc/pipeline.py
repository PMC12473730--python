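"""Experiment orchestration: generate -> solve -> metrics -> uncertainty /
sensitivity -> machine learning, from a single configuration, with a
reproducibility manifest.

Each stage writes its outputs under the experiment directory (CSV/JSON);
the manifest records the configuration hash, package version, seeds and
per-stage wall status so every output file is traceable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .body import default_model, load_model
from .config import ExperimentConfig, config_hash
from .metrics import peak_metrics, adaptation_proxies, summarize_outcome
from .ml import (ModelSpec, build_feature_table, feature_importance,
                 make_target, residual_diagnostics, split_dataset,
                 standardize_features, tune_and_fit)
from .optimize import solve_trajectory
from .sensitivity import (convergence_study, default_ranges, load_ranges,
                          lhs_sweep, oat_sweep, one_rm_outcomes,
                          trial_outcomes)
from .tasks import (TaskSpec, default_tasks, estimate_1rm, generate_trial,
                    load_tasks)

__all__ = ["run_experiment", "quiet_stance_spec", "write_trace"]

log = logging.getLogger("neuromusc")

UNCERTAINTY_OUTCOMES = ("peak_vgrf", "rfd", "peak_moment_hip",
                        "peak_moment_knee", "peak_moment_ankle", "synchrony")


def quiet_stance_spec(duration_s: float = 3.0, fs_hz: float = 1000.0,
                      replicates: int = 10) -> TaskSpec:
    """The unloaded quiet-stance scenario used as the SMD baseline."""
    return TaskSpec(
        name="quiet_stance", kind="strength", duration_s=duration_s,
        fs_hz=fs_hz, replicates=replicates,
        stance_deg=(10.0, 15.0, 5.0), bottom_deg=(12.0, 18.0, 6.0),
        knee_bottom_range_deg=(0.0, 30.0), trunk_limit_deg=(0.0, 10.0),
        loads=(0.0,), default_load=0.0)


def write_trace(trial, model, path: Path) -> None:
    """Tidy long-format trace CSV: time_s, joint/channel, value, units."""
    frames = []
    for j, joint in enumerate(("hip", "knee", "ankle")):
        frames.append(pd.DataFrame({
            "time_s": trial.t, "channel": f"angle_{joint}",
            "value": trial.q[:, j], "units": "rad"}))
        frames.append(pd.DataFrame({
            "time_s": trial.t, "channel": f"moment_{joint}",
            "value": trial.tau[:, j], "units": "Nm_per_leg"}))
    frames.append(pd.DataFrame({
        "time_s": trial.t, "channel": "grf_vertical",
        "value": trial.grf[:, 1], "units": "N"}))
    frames.append(pd.DataFrame({
        "time_s": trial.t, "channel": "grf_ap",
        "value": trial.grf[:, 0], "units": "N"}))
    if trial.activations is not None:
        for i, name in enumerate(model.muscle_names):
            frames.append(pd.DataFrame({
                "time_s": trial.t, "channel": f"act_{name}",
                "value": trial.activations[:, i], "units": "1"}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    meta = {"task": trial.task.name, "replicate": trial.replicate,
            "seed": trial.seed, "model_mass": model.mass,
            "load_fraction": trial.load_fraction, "meta": trial.meta}
    path.with_suffix(".json").write_text(json.dumps(meta, default=str,
                                                    indent=1))


def run_experiment(cfg: ExperimentConfig, stages=("generate", "metrics",
                                                  "sensitivity", "ml")
                   ) -> dict:
    """Execute the pipeline stages in order; returns the report bundle."""
    t_start = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": config_hash(cfg), "version": __version__,
                "seed": cfg.seed, "stages": {}}

    model = (default_model() if cfg.model_file is None
             else load_model(cfg.model_file))
    tasks = (default_tasks() if cfg.tasks_file is None
             else load_tasks(cfg.tasks_file))
    ranges = (default_ranges() if cfg.ranges_file is None
              else load_ranges(cfg.ranges_file))
    bundle: dict = {"model": model, "tasks": tasks, "config": cfg}

    def stage(name):
        return name in stages

    # ---- generate + solve -------------------------------------------------
    t0 = time.time()
    max_moments = estimate_1rm(model)
    bundle["max_moments"] = max_moments
    trials = []
    n_invalid = 0
    for tname, spec in tasks.items():
        reps = cfg.replicates or spec.replicates
        for rep in range(reps):
            trial = generate_trial(spec, rep, cfg.seed, model,
                                   max_moments=max_moments,
                                   load_fraction=(cfg.load_fraction
                                                  if spec.kind == "strength"
                                                  else None))
            trial = solve_trajectory(trial, model)
            if not trial.solver_flags.get("valid", True):
                n_invalid += 1
                log.warning("invalid trial %s rep %d: %s", tname, rep,
                            trial.meta.get("invalid_reason"))
            trials.append(trial)
    # baseline scenario for SMDs
    base_spec = quiet_stance_spec()
    base_trials = [solve_trajectory(
        generate_trial(base_spec, rep, cfg.seed, model), model)
        for rep in range(base_spec.replicates)]
    bundle["trials"] = trials
    bundle["baseline_trials"] = base_trials
    manifest_rows = [{"task": tr.task.name, "replicate": tr.replicate,
                      "seed": tr.seed, "load_fraction": tr.load_fraction,
                      "valid": tr.solver_flags.get("valid", True)}
                     for tr in trials]
    pd.DataFrame(manifest_rows).to_csv(out / "trial_manifest.csv",
                                       index=False)
    if cfg.write_traces:
        tdir = out / "traces"
        tdir.mkdir(exist_ok=True)
        for tr in trials:
            write_trace(tr, model,
                        tdir / f"{tr.task.name}_r{tr.replicate:02d}.csv")
    manifest["stages"]["generate"] = {
        "n_trials": len(trials), "n_invalid": n_invalid,
        "wall_s": round(time.time() - t0, 2)}

    # ---- metrics + uncertainty -------------------------------------------
    if stage("metrics"):
        t0 = time.time()
        msets = [peak_metrics(tr, model) for tr in trials]
        base_msets = [peak_metrics(tr, model) for tr in base_trials]
        bundle["metric_sets"] = msets
        mdf = pd.DataFrame([dict(task=m.task, replicate=m.replicate,
                                 **m.scalar_fields()) for m in msets])
        from .metrics import METRIC_UNITS
        mdf.columns = [f"{c} [{METRIC_UNITS[c]}]" if c in METRIC_UNITS
                       else c for c in mdf.columns]
        mdf.to_csv(out / "metrics.csv", index=False)
        # across-replicate waveform variability (percent CV) per task/joint
        from .metrics import moment_variability
        var_rows = []
        for tname, spec in tasks.items():
            reps = [tr for tr in trials if tr.task.name == tname]
            if len(reps) < 2:
                continue
            for j, joint in enumerate(("hip", "knee", "ankle")):
                waves = [tr.tau[tr.contact, j] for tr in reps]
                var_rows.append({"task": tname, "joint": joint,
                                 "cv_pct": moment_variability(waves)})
        pd.DataFrame(var_rows).to_csv(out / "moment_variability.csv",
                                      index=False)
        proxies = adaptation_proxies(msets)
        bundle["proxies"] = proxies
        pd.DataFrame([dataclasses.asdict(p) for p in proxies]).to_csv(
            out / "proxies.csv", index=False)
        summaries = []
        for tname in {m.task for m in msets}:
            for outcome in UNCERTAINTY_OUTCOMES:
                reps = [getattr(m, outcome) for m in msets
                        if m.task == tname]
                base = float(np.median([getattr(m, outcome)
                                        for m in base_msets]))
                if np.any(~np.isfinite(reps)) or len(reps) < 5:
                    continue   # BCa needs at least 5 replicates
                s = summarize_outcome(f"{tname}:{outcome}", reps, base,
                                      B=cfg.uq.bootstrap_B, seed=cfg.seed)
                summaries.append(dataclasses.asdict(s))
        (out / "uncertainty.json").write_text(
            json.dumps(summaries, indent=1))
        bundle["uncertainty"] = summaries
        manifest["stages"]["metrics"] = {
            "n_outcomes": len(summaries),
            "wall_s": round(time.time() - t0, 2)}

    # ---- sensitivity -------------------------------------------------------
    if stage("sensitivity"):
        t0 = time.time()
        if cfg.sensitivity.outcome == "one_rm":
            fn = lambda d: one_rm_outcomes(model, d)    # noqa: E731
        else:
            spec = tasks[cfg.sensitivity.outcome]
            fn = lambda d: trial_outcomes(model, d, spec,   # noqa: E731
                                          seed=cfg.seed,
                                          max_moments=max_moments)
        oat = oat_sweep(fn, ranges, levels=cfg.sensitivity.oat_levels)
        lhs = lhs_sweep(fn, ranges, n=cfg.sensitivity.lhs_n, seed=cfg.seed)
        oat.deviations.to_csv(out / "oat_deviations.csv", index=False)
        lhs.design.assign(**{c: lhs.outcomes[c]
                             for c in lhs.outcomes.columns}).to_csv(
            out / "lhs_draws.csv", index=False)
        lhs.coefficients.to_csv(out / "standardized_coefficients.csv")
        (out / "tornado.json").write_text(json.dumps(
            {"oat": oat.tornado, "lhs": lhs.tornado}, indent=1))
        bundle["sensitivity"] = {"oat": oat, "lhs": lhs}
        if cfg.sensitivity.run_convergence:
            conv = convergence_study(model, tasks, seed=cfg.seed)
            conv.to_csv(out / "convergence.csv", index=False)
            bundle["convergence"] = conv
        manifest["stages"]["sensitivity"] = {
            "lhs_n": cfg.sensitivity.lhs_n,
            "wall_s": round(time.time() - t0, 2)}

    # ---- machine learning ---------------------------------------------------
    if stage("ml"):
        t0 = time.time()
        msets = bundle.get("metric_sets") or [peak_metrics(tr, model)
                                              for tr in trials]
        y = make_target(msets, noise_frac=cfg.ml.target_noise,
                        seed=cfg.seed)
        df = build_feature_table(trials, model, metric_sets=msets, target=y)
        df = split_dataset(df, ratios=tuple(cfg.ml.split_ratios),
                           seed=cfg.seed)
        table = standardize_features(df)
        table.frame.to_csv(out / "feature_table.csv", index=False)
        reports = {}
        for family in cfg.ml.families:
            mspec = ModelSpec(family=family, budget=cfg.ml.budget,
                              folds=cfg.ml.folds, tuning=cfg.ml.tuning,
                              seed=cfg.seed,
                              pca_variance=cfg.ml.pca_variance)
            rep = tune_and_fit(mspec, table)
            if family in ("random_forest", "gradient_boosting"):
                params = {k: v for k, v in rep.best_params.items()}
                rep.importance, rep.permutation = feature_importance(
                    table, family=family, B=cfg.uq.bootstrap_B,
                    seed=cfg.seed, params=params)
            ev = table.frame[table.frame["split"].isin(["val", "test"])]
            y_ev = ev["target"].to_numpy()
            X_ev = ev[table.feature_cols].to_numpy(dtype=float)
            try:
                rep.diagnostics = residual_diagnostics(
                    y_ev, rep.estimator.predict(X_ev),
                    out_dir=out / "plots", prefix=family)
            except ValueError as exc:
                rep.diagnostics = {"skipped": str(exc)}
            reports[family] = rep
            pairs = [("back_squat", "DJ50"), ("deadlift", "DJ50"),
                     ("leg_press", "CMJ")]
            try:
                from .ml import predict_combined
                combined = predict_combined(rep, table, pairs)
                combined.to_csv(out / f"combined_{family}.csv",
                                index=False)
            except ValueError:
                combined = None
            payload = {
                "family": family, "best_params": rep.best_params,
                "cv_metrics": rep.cv_metrics,
                "test_metrics": rep.test_metrics,
                "diagnostics": {k: v for k, v in rep.diagnostics.items()
                                if not isinstance(v, pd.DataFrame)},
            }
            if rep.importance is not None:
                payload["importance_top10"] = rep.importance.head(10).to_dict(
                    orient="records")
            (out / f"fit_{family}.json").write_text(
                json.dumps(payload, indent=1, default=str))
        bundle["fit_reports"] = reports
        manifest["stages"]["ml"] = {
            "families": list(cfg.ml.families),
            "wall_s": round(time.time() - t0, 2)}

    manifest["wall_s"] = round(time.time() - t_start, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    bundle["manifest"] = manifest
    return bundle
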