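"""Sensitivity and robustness machinery.

One-at-a-time (OAT) sweeps, Latin-hypercube global sampling over joint
parameter ranges, standardized regression coefficients, tornado rankings,
and the numerical-convergence audit over sampling-step / solver-accuracy
grids.

Perturbations act through named parameter families: common multipliers on
muscle F_max, optimal fiber length, tendon slack length and tendon
stiffness; anthropometric mass and segment-length multipliers (applied
through model rescaling); a foot-ground contact-stiffness multiplier
(amortization compliance scales with 1/sqrt(k)); and a zero-mean GRF
noise level applied before inverse dynamics.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from scipy.stats import qmc

from .body import ScaledModel, scale_model
from .dynamics import inverse_dynamics
from .metrics import peak_metrics
from .optimize import solve_trajectory
from .tasks import (TaskSpec, default_tasks, estimate_1rm, generate_trial,
                    inject_grf_noise)

__all__ = [
    "ParameterRange", "SweepResult", "load_ranges", "default_ranges",
    "lhs_sample", "apply_perturbation", "oat_sweep",
    "standardized_coefficients", "tornado_ranking", "convergence_study",
    "one_rm_outcomes", "trial_outcomes",
]


@dataclass(frozen=True)
class ParameterRange:
    """One perturbed parameter family."""

    name: str
    kind: str                    # 'multiplicative' | 'additive'
    lo: float
    hi: float
    baseline: float
    distribution: str = "uniform"   # 'uniform' | 'loguniform'

    def __post_init__(self):
        if self.kind not in ("multiplicative", "additive"):
            raise ValueError(f"{self.name}: unknown kind {self.kind!r}")
        if not self.lo <= self.baseline <= self.hi:
            raise ValueError(f"{self.name}: baseline outside [lo, hi]")

    def sample(self, u):
        """Map uniform(0,1) draws into the range."""
        u = np.asarray(u, dtype=float)
        if self.distribution == "loguniform":
            return np.exp(np.log(self.lo)
                          + u * (np.log(self.hi) - np.log(self.lo)))
        return self.lo + u * (self.hi - self.lo)


@dataclass
class SweepResult:
    design: pd.DataFrame            # draws (baseline row included for OAT)
    outcomes: pd.DataFrame          # per-draw outcome values
    deviations: pd.DataFrame | None = None      # relative to baseline
    coefficients: pd.DataFrame | None = None    # standardized betas
    tornado: list | None = None                 # ranked parameter names


def load_ranges(source) -> list[ParameterRange]:
    if isinstance(source, dict):
        cfg = source
    elif hasattr(source, "read"):
        cfg = yaml.safe_load(source)
    else:
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
    out = []
    for name, c in cfg["ranges"].items():
        out.append(ParameterRange(
            name=name, kind=c["kind"], lo=float(c["lo"]), hi=float(c["hi"]),
            baseline=float(c["baseline"]),
            distribution=c.get("distribution", "uniform")))
    return out


def default_ranges() -> list[ParameterRange]:
    ref = importlib.resources.files("neuromusc.data") / "ranges_default.yaml"
    with ref.open() as fh:
        return load_ranges(fh)


def ranges_to_config(ranges) -> dict:
    """Inverse of :func:`load_ranges` (config round-trip)."""
    out = {}
    for r in ranges:
        d = {"kind": r.kind, "lo": r.lo, "hi": r.hi, "baseline": r.baseline}
        if r.distribution != "uniform":
            d["distribution"] = r.distribution
        out[r.name] = d
    return {"ranges": out}


# ---------------------------------------------------------------------------
# sampling


def lhs_sample(ranges, n: int = 200, seed: int = 0) -> pd.DataFrame:
    """Latin-hypercube design: each parameter's n draws occupy n distinct
    equal-probability strata, randomly paired across parameters."""
    if not ranges:
        raise ValueError("need at least one parameter range")
    sampler = qmc.LatinHypercube(d=len(ranges), rng=np.random.default_rng(seed))
    u = sampler.random(n)
    cols = {r.name: r.sample(u[:, j]) for j, r in enumerate(ranges)}
    return pd.DataFrame(cols)


def apply_perturbation(model: ScaledModel, draw: dict) -> tuple[ScaledModel, dict]:
    """Apply one parameter draw; returns the perturbed model and the
    task-level settings (contact multiplier, GRF noise level)."""
    m = model
    mass_mult = draw.get("mass_mult", 1.0)
    length_mult = draw.get("length_mult", 1.0)
    if mass_mult != 1.0 or length_mult != 1.0:
        m = scale_model(m.height * length_mult, m.mass * mass_mult, m)
    muscle_mults = {
        "F_max": draw.get("fmax_mult", 1.0),
        "l_opt": draw.get("lopt_mult", 1.0),
        "l_slack": draw.get("lslack_mult", 1.0),
        "k_T": draw.get("tendon_k_mult", 1.0),
    }
    if any(v != 1.0 for v in muscle_mults.values()):
        m = m.with_muscles(mu.with_multipliers(
            F_max=muscle_mults["F_max"], l_opt=muscle_mults["l_opt"],
            l_slack=muscle_mults["l_slack"], k_T=muscle_mults["k_T"])
            for mu in m.muscles)
    settings = {"contact_mult": draw.get("contact_mult", 1.0),
                "grf_noise_level": draw.get("grf_noise_level", 0.0)}
    return m, settings


# ---------------------------------------------------------------------------
# outcome functions


def one_rm_outcomes(model: ScaledModel, draw: dict,
                    tasks=None, rigid_tendon=False) -> dict:
    """Fast outcome set: maximal feasible joint moments (Nm/kg)."""
    pm, _ = apply_perturbation(model, draw)
    table = estimate_1rm(pm, tasks=tasks, rigid_tendon=rigid_tendon)
    out = {}
    for ex, row in table.normalized.items():
        for j, v in row.items():
            out[f"{ex}_{j}"] = v
    return out


def trial_outcomes(model: ScaledModel, draw: dict, spec: TaskSpec,
                   seed: int = 0, max_moments=None) -> dict:
    """Full outcome set: metrics of one regenerated, re-solved trial
    (RFD, peak moments, peak activations, synchrony)."""
    pm, settings = apply_perturbation(model, draw)
    trial = generate_trial(spec, 0, seed, pm, max_moments=max_moments,
                           contact_stiffness=settings["contact_mult"])
    level = settings["grf_noise_level"]
    if level > 0:
        noisy = inject_grf_noise(trial.grf, level, seed)
        ext = np.stack([np.zeros(len(trial.t)), -trial.load_force], axis=-1)
        idr = inverse_dynamics(trial.t, trial.q, noisy, trial.cop_x, pm,
                               base=trial.base, contact=trial.contact,
                               ext_force=ext,
                               ext_line_x=np.full(len(trial.t),
                                                  trial.ext_line_x))
        trial.grf = noisy
        trial.tau = idr.tau_per_leg
        trial.residual_force = idr.residual_force
    trial = solve_trajectory(trial, pm)
    ms = peak_metrics(trial, pm)
    out = {k: v for k, v in ms.scalar_fields().items()
           if k in ("rfd", "peak_vgrf", "peak_moment_hip",
                    "peak_moment_knee", "peak_moment_ankle", "synchrony")}
    acts = [v for k, v in ms.peak_activations.items()]
    out["peak_activation_max"] = float(max(acts))
    return out


# ---------------------------------------------------------------------------
# sweeps


def oat_sweep(outcome_fn, ranges, levels: int = 3) -> SweepResult:
    """One-at-a-time sweep: each parameter at ``levels`` values across its
    range (others at baseline); relative deviations and tornado ranking."""
    base_draw = {r.name: r.baseline for r in ranges}
    rows = [dict(base_draw, _param="baseline", _level=0.0)]
    for r in ranges:
        for v in np.linspace(r.lo, r.hi, levels):
            if np.isclose(v, r.baseline):
                continue
            d = dict(base_draw)
            d[r.name] = float(v)
            rows.append(dict(d, _param=r.name, _level=float(v)))
    out_rows = []
    for d in rows:
        draw = {k: v for k, v in d.items() if not k.startswith("_")}
        try:
            out_rows.append(outcome_fn(draw))
        except Exception:   # failed re-simulation: recorded as missing
            out_rows.append({})
    design = pd.DataFrame(rows)
    outcomes = pd.DataFrame(out_rows)
    base = outcomes.iloc[0]
    dev = (outcomes - base) / base.abs().replace(0.0, np.nan)
    dev.insert(0, "_param", design["_param"].values)
    result = SweepResult(design=design, outcomes=outcomes, deviations=dev)
    result.tornado = tornado_ranking(dev)
    return result


def tornado_ranking(deviations: pd.DataFrame) -> list:
    """Parameters ranked by their maximum absolute relative deviation."""
    dev = deviations[deviations["_param"] != "baseline"]
    mags = (dev.drop(columns="_param").abs()
            .groupby(dev["_param"]).max().max(axis=1))
    return list(mags.sort_values(ascending=False).index)


def standardized_coefficients(design: pd.DataFrame,
                              outcomes: pd.DataFrame) -> pd.DataFrame:
    """Standardized OLS regression coefficients per outcome.

    Inputs and outputs are z-scored; rows = parameters, columns =
    outcomes. Raises on rank-deficient designs.
    """
    X = design.select_dtypes(include=[np.number])
    if len(X) <= X.shape[1] + 1:
        raise ValueError("need more draws than parameters + 1")
    Xz = (X - X.mean()) / X.std(ddof=0)
    if np.linalg.matrix_rank(Xz.values) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    A = np.column_stack([np.ones(len(Xz)), Xz.values])
    betas = {}
    for col in outcomes.columns:
        y = outcomes[col].to_numpy(dtype=float)
        sd = y.std(ddof=0)
        yz = (y - y.mean()) / sd if sd > 1e-15 else np.zeros_like(y)
        coef, *_ = np.linalg.lstsq(A, yz, rcond=None)
        betas[col] = coef[1:]
    return pd.DataFrame(betas, index=X.columns)


def lhs_sweep(outcome_fn, ranges, n: int = 200, seed: int = 0) -> SweepResult:
    """Latin-hypercube sweep with standardized-coefficient summary."""
    design = lhs_sample(ranges, n=n, seed=seed)
    outs = pd.DataFrame([outcome_fn(dict(row)) for _, row in design.iterrows()])
    coefs = standardized_coefficients(design, outs)
    result = SweepResult(design=design, outcomes=outs, coefficients=coefs)
    result.tornado = list(coefs.abs().max(axis=1)
                          .sort_values(ascending=False).index)
    return result


# ---------------------------------------------------------------------------
# numerical convergence


def convergence_study(model: ScaledModel, tasks=None,
                      dt_list=(0.0005, 0.001, 0.002),
                      acc_list=(1e-4, 1e-5, 1e-6),
                      baseline=(0.001, 1e-5), seed: int = 0,
                      task_names=("DJ50", "back_squat")) -> pd.DataFrame:
    """Percent change of RFD, peak moments and synchrony across the
    sampling-step x solver-accuracy grid, relative to the baseline
    setting. In this quasi-static pipeline the 'integrator' settings map
    to the trace sampling step and the per-frame solver tolerance."""
    if tasks is None:
        tasks = default_tasks()
    t1rm = estimate_1rm(model)

    def run(task, dt, acc):
        tr = generate_trial(tasks[task], 0, seed, model,
                            max_moments=t1rm, dt=dt)
        tr = solve_trajectory(tr, model, tol=acc)
        ms = peak_metrics(tr, model)
        return {"rfd": ms.rfd, "peak_moment_hip": ms.peak_moment_hip,
                "peak_moment_knee": ms.peak_moment_knee,
                "peak_moment_ankle": ms.peak_moment_ankle,
                "synchrony": ms.synchrony}

    rows = []
    for task in task_names:
        ref = run(task, *baseline)
        for dt in dt_list:
            for acc in acc_list:
                cur = run(task, dt, acc)
                row = {"task": task, "dt": dt, "accuracy": acc}
                for k in ref:
                    row[f"pct_change_{k}"] = (
                        100.0 * abs(cur[k] - ref[k]) / max(abs(ref[k]), 1e-12))
                rows.append(row)
    return pd.DataFrame(rows)
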